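"""Layers and optimizer built on the autodiff engine.

Conventions follow the usual deep-learning ones: activations are
(N, C, H, W), convolutions are cross-correlations, "deconvolution" layers
are stride-1 transposed convolutions (kernel flipped and in/out channels
swapped relative to a forward convolution), and batch normalization keeps
exponential running statistics for evaluation mode.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import ShapeError


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with parameter discovery and train/eval mode switching."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self):
        for prefix, mod in self._named_modules():
            for key, val in mod.__dict__.items():
                if isinstance(val, Parameter):
                    yield (f"{prefix}{key}", val)

    def _named_modules(self, prefix=""):
        yield (prefix, self)
        for key, val in self.__dict__.items():
            if isinstance(val, Module):
                yield from val._named_modules(f"{prefix}{key}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item._named_modules(f"{prefix}{key}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, flag: bool = True):
        for m in self.modules():
            m.training = flag
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for prefix, mod in self._named_modules():
            if isinstance(mod, BatchNorm2d):
                state[f"{prefix}running_mean"] = mod.running_mean.copy()
                state[f"{prefix}running_var"] = mod.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for name, p in self.named_parameters():
            p.data = np.array(state[name], dtype=np.float64)
        for prefix, mod in self._named_modules():
            if isinstance(mod, BatchNorm2d):
                mod.running_mean = np.array(state[f"{prefix}running_mean"])
                mod.running_var = np.array(state[f"{prefix}running_var"])


class Conv2d(Module):
    """Same-padding 2-D convolution with Gaussian-initialized weights."""

    def __init__(self, in_ch, out_ch, kernel, rng, init_std, bias=True):
        super().__init__()
        if kernel % 2 == 0:
            raise ShapeError("only odd kernel sizes are supported")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.padding = (kernel - 1) // 2
        self.weight = Parameter(
            rng.normal(0.0, init_std, size=(out_ch, in_ch, kernel, kernel))
        )
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, padding=self.padding)


class Deconv2d(Module):
    """Stride-1 transposed convolution preserving spatial size.

    With stride 1 and same padding this is the adjoint of :class:`Conv2d`:
    the stored weight has shape (in_ch, out_ch, k, k) and is flipped and
    channel-swapped before the underlying correlation.
    """

    def __init__(self, in_ch, out_ch, kernel, rng, init_std, bias=True):
        super().__init__()
        if kernel % 2 == 0:
            raise ShapeError("only odd kernel sizes are supported")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.padding = (kernel - 1) // 2
        self.weight = Parameter(
            rng.normal(0.0, init_std, size=(in_ch, out_ch, kernel, kernel))
        )
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        w = ad.swap_in_out(ad.flip_spatial(self.weight))
        return ad.conv2d(x, w, self.bias, padding=self.padding)


class BatchNorm2d(Module):
    """Batch normalization with running statistics.

    ``frozen_stats`` — set temporarily during the second forward pass of a
    mechanism training step — reuses the batch moments cached by the first
    pass (treated as constants) and leaves the running statistics untouched,
    so one optimization step updates the statistics exactly once.
    """

    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.frozen_stats = False
        self._cached = None

    def __call__(self, x: Tensor) -> Tensor:
        if x.data.shape[1] != self.channels:
            raise ShapeError(
                f"batch norm expects {self.channels} channels, got {x.data.shape[1]}"
            )
        if self.training and not self.frozen_stats:
            mean_c = x.data.mean(axis=(0, 2, 3))
            var_c = x.data.var(axis=(0, 2, 3))
            self._cached = (mean_c, var_c)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean_c
            self.running_var = (1 - m) * self.running_var + m * var_c
            return ad.batch_norm2d(
                x, self.gamma, self.beta, mean_c, var_c, self.eps, True
            )
        if self.training and self.frozen_stats and self._cached is not None:
            mean_c, var_c = self._cached
        else:
            mean_c, var_c = self.running_mean, self.running_var
        return ad.batch_norm2d(x, self.gamma, self.beta, mean_c, var_c, self.eps, False)


class frozen_batch_stats:
    """Context manager freezing batch-norm statistics across a model."""

    def __init__(self, model: Module):
        self.bns = [m for m in model.modules() if isinstance(m, BatchNorm2d)]

    def __enter__(self):
        for bn in self.bns:
            bn.frozen_stats = True
        return self

    def __exit__(self, *exc):
        for bn in self.bns:
            bn.frozen_stats = False
        return False


class Adam:
    """Adam optimizer (Kingma & Ba) over a parameter list."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
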