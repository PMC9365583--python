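"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is the compute backend for the denoising network and its losses. It
implements exactly the operator set the package needs — elementwise
arithmetic, reductions, 2-D convolution (via strided im2col), pooling,
nearest-neighbour upsampling, channel concatenation and batch
normalization — with analytic backward passes. Every primitive is verified
against central finite differences in the test suite.

Tensors are double precision throughout: training runs here are small, and
exact reproducibility plus easy comparison against brute-force oracles are
worth more than speed.
"""

from __future__ import annotations

import numpy as np

from .errors import ShapeError

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "sub",
    "mul",
    "div",
    "neg",
    "power",
    "relu",
    "clamp_min",
    "mean",
    "total",
    "conv2d",
    "max_pool2d",
    "avg_pool2d",
    "upsample2x",
    "concat_channels",
    "batch_norm2d",
    "flip_spatial",
    "swap_in_out",
]


class Tensor:
    """An array node in the computation graph.

    ``requires_grad`` marks trainable leaves; interior nodes receive
    gradients whenever anything upstream of them is trainable.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # -- graph mechanics ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _needs_grad(self) -> bool:
        return self.requires_grad or bool(self._parents)

    def backward(self, grad=None) -> None:
        """Accumulate gradients of ``self`` into every upstream tensor."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if id(node) in seen:
                continue
            if expanded:
                seen.add(id(node))
                topo.append(node)
            else:
                stack.append((node, True))
                for p in node._parents:
                    if id(p) not in seen:
                        stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, g) -> None:
        if not self._needs_grad():
            return
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    # -- operator sugar ----------------------------------------------------

    def __add__(self, other):
        return add(self, as_tensor(other))

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, as_tensor(other))

    def __rsub__(self, other):
        return sub(as_tensor(other), self)

    def __mul__(self, other):
        return mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, as_tensor(other))

    def __rtruediv__(self, other):
        return div(as_tensor(other), self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, exponent):
        return power(self, exponent)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _binary(a: Tensor, b: Tensor, out_data, da_fn, db_fn) -> Tensor:
    out = Tensor(out_data, _parents=(a, b))

    def _backward(g):
        a._accumulate(_unbroadcast(da_fn(g), a.data.shape))
        b._accumulate(_unbroadcast(db_fn(g), b.data.shape))

    out._backward = _backward
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    return _binary(a, b, a.data + b.data, lambda g: g, lambda g: g)


def sub(a: Tensor, b: Tensor) -> Tensor:
    return _binary(a, b, a.data - b.data, lambda g: g, lambda g: -g)


def mul(a: Tensor, b: Tensor) -> Tensor:
    return _binary(a, b, a.data * b.data, lambda g: g * b.data, lambda g: g * a.data)


def div(a: Tensor, b: Tensor) -> Tensor:
    return _binary(
        a,
        b,
        a.data / b.data,
        lambda g: g / b.data,
        lambda g: -g * a.data / (b.data * b.data),
    )


def neg(a: Tensor) -> Tensor:
    out = Tensor(-a.data, _parents=(a,))
    out._backward = lambda g: a._accumulate(-g)
    return out


def power(a: Tensor, exponent: float) -> Tensor:
    e = float(exponent)
    out = Tensor(np.power(a.data, e), _parents=(a,))
    out._backward = lambda g: a._accumulate(g * e * np.power(a.data, e - 1.0))
    return out


def clamp_min(a: Tensor, floor: float) -> Tensor:
    """Elementwise maximum with a constant; gradient flows where a > floor."""
    out = Tensor(np.maximum(a.data, floor), _parents=(a,))
    out._backward = lambda g: a._accumulate(g * (a.data > floor))
    return out


def relu(a: Tensor) -> Tensor:
    out = Tensor(np.maximum(a.data, 0.0), _parents=(a,))
    out._backward = lambda g: a._accumulate(g * (a.data > 0.0))
    return out


def mean(a: Tensor) -> Tensor:
    n = a.data.size
    out = Tensor(a.data.mean(), _parents=(a,))
    out._backward = lambda g: a._accumulate(np.full_like(a.data, float(g) / n))
    return out


def total(a: Tensor) -> Tensor:
    out = Tensor(a.data.sum(), _parents=(a,))
    out._backward = lambda g: a._accumulate(np.full_like(a.data, float(g)))
    return out


# -- convolution ----------------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """View of shape (N, C, kh, kw, Ho, Wo) over all valid patches."""
    n, c, h, w = x.shape
    ho, wo = h - kh + 1, w - kw + 1
    s0, s1, s2, s3 = x.strides
    return np.lib.stride_tricks.as_strided(
        x, (n, c, kh, kw, ho, wo), (s0, s1, s2, s3, s2, s3), writeable=False
    )


def _corr2d(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Valid cross-correlation of (N,C,H,W) with (F,C,kh,kw) -> (N,F,Ho,Wo)."""
    cols = _im2col(x, w.shape[2], w.shape[3])
    out = np.tensordot(w, cols, axes=([1, 2, 3], [1, 2, 3]))
    return np.ascontiguousarray(out.transpose(1, 0, 2, 3))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 0) -> Tensor:
    """2-D cross-correlation with optional zero padding and bias.

    x: (N, C, H, W); w: (F, C, kh, kw); b: (F,). Output spatial size is
    H - kh + 1 + 2*padding (the "valid" region of the padded input).
    """
    if x.data.ndim != 4 or w.data.ndim != 4:
        raise ShapeError("conv2d expects 4-D input and weight")
    if x.data.shape[1] != w.data.shape[1]:
        raise ShapeError(
            f"conv2d channel mismatch: input has {x.data.shape[1]}, "
            f"weight expects {w.data.shape[1]}"
        )
    kh, kw = w.data.shape[2], w.data.shape[3]
    pad = int(padding)
    xp = (
        np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        if pad
        else x.data
    )
    if xp.shape[2] < kh or xp.shape[3] < kw:
        raise ShapeError("conv2d input smaller than kernel")
    out_data = _corr2d(xp, w.data)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, _parents=parents)

    def _backward(g):
        g = np.ascontiguousarray(g)
        if w._needs_grad():
            cols = _im2col(xp, kh, kw)
            # dw[f,c,i,j] = sum_{n,ho,wo} g[n,f,ho,wo] * xp[n,c,ho+i,wo+j]
            dw = np.tensordot(g, cols, axes=([0, 2, 3], [0, 4, 5]))
            w._accumulate(dw)
        if b is not None and b._needs_grad():
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x._needs_grad():
            # full correlation of g with the flipped, in/out-swapped kernel
            wf = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            gp = np.pad(g, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
            dxp = _corr2d(gp, np.ascontiguousarray(wf))
            if pad:
                dxp = dxp[:, :, pad:-pad, pad:-pad]
            x._accumulate(dxp)

    out._backward = _backward
    return out


def flip_spatial(w: Tensor) -> Tensor:
    """Flip the last two axes (differentiable index permutation)."""
    out = Tensor(w.data[..., ::-1, ::-1].copy(), _parents=(w,))
    out._backward = lambda g: w._accumulate(g[..., ::-1, ::-1])
    return out


def swap_in_out(w: Tensor) -> Tensor:
    """Swap the first two axes of a conv weight (differentiable)."""
    out = Tensor(np.ascontiguousarray(w.data.transpose(1, 0, 2, 3)), _parents=(w,))
    out._backward = lambda g: w._accumulate(g.transpose(1, 0, 2, 3))
    return out


# -- pooling / resampling --------------------------------------------------


def _blockify(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    return (
        x.reshape(n, c, h // 2, 2, w // 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h // 2, w // 2, 4)
    )


def max_pool2d(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2. Spatial dims must be even."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ShapeError("max_pool2d requires even spatial dimensions")
    blocks = _blockify(x.data)
    idx = blocks.argmax(axis=-1)
    out_data = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
    out = Tensor(out_data, _parents=(x,))

    def _backward(g):
        db = np.zeros_like(blocks)
        np.put_along_axis(db, idx[..., None], g[..., None], axis=-1)
        dx = (
            db.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        x._accumulate(dx)

    out._backward = _backward
    return out


def avg_pool2d(x: Tensor) -> Tensor:
    """2x2 average pooling, stride 2."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ShapeError("avg_pool2d requires even spatial dimensions")
    out_data = _blockify(x.data).mean(axis=-1)
    out = Tensor(out_data, _parents=(x,))

    def _backward(g):
        x._accumulate(np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0)

    out._backward = _backward
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    out = Tensor(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3), _parents=(x,))

    def _backward(g):
        x._accumulate(_blockify(g).sum(axis=-1))

    out._backward = _backward
    return out


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape[0] != b.data.shape[0] or a.data.shape[2:] != b.data.shape[2:]:
        raise ShapeError("concat_channels requires matching batch and spatial dims")
    ca = a.data.shape[1]
    out = Tensor(np.concatenate([a.data, b.data], axis=1), _parents=(a, b))

    def _backward(g):
        a._accumulate(g[:, :ca])
        b._accumulate(g[:, ca:])

    out._backward = _backward
    return out


def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    mean_c: np.ndarray,
    var_c: np.ndarray,
    eps: float,
    stats_from_batch: bool,
) -> Tensor:
    """Per-channel normalization with affine parameters.

    ``mean_c`` / ``var_c`` are the statistics to normalize with. When
    ``stats_from_batch`` is true they are the current batch's moments and the
    backward pass uses the full batch-norm gradient; otherwise they are
    treated as constants (running or frozen statistics).
    """
    if x.data.ndim != 4:
        raise ShapeError("batch_norm2d expects (N, C, H, W) input")
    std = np.sqrt(var_c + eps)
    xhat = (x.data - mean_c[None, :, None, None]) / std[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    out = Tensor(out_data, _parents=(x, gamma, beta))

    def _backward(g):
        if gamma._needs_grad():
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta._needs_grad():
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x._needs_grad():
            gg = g * gamma.data[None, :, None, None]
            if stats_from_batch:
                mean_g = gg.mean(axis=(0, 2, 3), keepdims=True)
                mean_gx = (gg * xhat).mean(axis=(0, 2, 3), keepdims=True)
                dx = (gg - mean_g - xhat * mean_gx) / std[None, :, None, None]
            else:
                dx = gg / std[None, :, None, None]
            x._accumulate(dx)

    out._backward = _backward
    return out
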