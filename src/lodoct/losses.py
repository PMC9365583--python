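"""Training losses: MSE, multi-scale SSIM, gradient loss, and combinations.

All losses accept NumPy arrays or autodiff tensors shaped (N, 1, H, W) or
plain 2-D images, return a scalar tensor (use ``.item()`` for the float),
are non-negative, and are exactly zero when prediction equals target.

The composite loss is the weighted sum

    L = lambda1 * L_MSE + lambda2 * L_MS-SSIM + lambda3 * L_grad

with default weights (1, 0.15, 0.8), and one training step of the
mask-guided mechanism minimizes L_total = L_original + L_correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import ConfigurationError, NumericError, ShapeError

__all__ = [
    "LossWeights",
    "MsSsimParams",
    "GradientKernel",
    "mse_loss",
    "ms_ssim_loss",
    "gradient_loss",
    "composite_loss",
    "total_loss",
]

#: Per-scale exponents of the five-scale MS-SSIM, as conventionally printed.
#: They sum to 1.0001; they are used as printed, without renormalization.
MS_SSIM_SCALE_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)

#: Fixed high-pass kernel of the gradient loss (zero-sum: constant images
#: produce zero response).
HIGH_PASS_KERNEL = np.array(
    [[-1.0, -1.0, -1.0], [0.0, 0.0, 0.0], [1.0, 1.0, 1.0]]
)


@dataclass
class LossWeights:
    lambda1: float = 1.0  # MSE
    lambda2: float = 0.15  # MS-SSIM
    lambda3: float = 0.8  # gradient

    def validate(self) -> "LossWeights":
        for name in ("lambda1", "lambda2", "lambda3"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        return self


@dataclass
class MsSsimParams:
    """Constants of the MS-SSIM loss.

    ``max_value`` is the dynamic range of the (normalized) images; the
    stability constants are C1 = (0.01*max)^2, C2 = (0.03*max)^2, C3 = C2/2.
    With fewer than five scales the leading ``n_scales`` weights are
    renormalized to sum to one.
    """

    scale_weights: tuple = MS_SSIM_SCALE_WEIGHTS
    n_scales: int = 5
    window_size: int = 11
    window_sigma: float = 1.5
    max_value: float = 1.0

    @property
    def c1(self) -> float:
        return (0.01 * self.max_value) ** 2

    @property
    def c2(self) -> float:
        return (0.03 * self.max_value) ** 2

    @property
    def c3(self) -> float:
        return self.c2 / 2.0

    def effective_weights(self) -> np.ndarray:
        if not 1 <= self.n_scales <= len(self.scale_weights):
            raise ConfigurationError(
                f"n_scales must be in [1, {len(self.scale_weights)}], got {self.n_scales}"
            )
        w = np.asarray(self.scale_weights[: self.n_scales], dtype=np.float64)
        if self.n_scales < len(self.scale_weights):
            w = w / w.sum()
        return w

    def validate(self) -> "MsSsimParams":
        self.effective_weights()
        if self.window_size % 2 == 0 or self.window_size < 3:
            raise ConfigurationError("window_size must be an odd integer >= 3")
        if self.window_sigma <= 0 or self.max_value <= 0:
            raise ConfigurationError("window_sigma and max_value must be > 0")
        return self


@dataclass
class GradientKernel:
    kernel: np.ndarray = field(default_factory=lambda: HIGH_PASS_KERNEL.copy())

    def validate(self) -> "GradientKernel":
        k = np.asarray(self.kernel, dtype=np.float64)
        if abs(k.sum()) > 1e-12:
            raise ConfigurationError("gradient kernel entries must sum to zero")
        self.kernel = k
        return self


def _as_batch(x) -> Tensor:
    t = ad.as_tensor(x)
    if t.data.ndim == 2:
        return ad.Tensor(t.data[None, None]) if not t._needs_grad() else _lift2d(t)
    if t.data.ndim == 3:  # (N, H, W)
        return _reshape_view(t, (t.data.shape[0], 1) + t.data.shape[1:])
    if t.data.ndim == 4:
        return t
    raise ShapeError(f"expected 2-D, 3-D or 4-D image data, got ndim={t.data.ndim}")


def _reshape_view(t: Tensor, shape) -> Tensor:
    out = Tensor(t.data.reshape(shape), _parents=(t,))
    out._backward = lambda g: t._accumulate(g.reshape(t.data.shape))
    return out


def _lift2d(t: Tensor) -> Tensor:
    return _reshape_view(t, (1, 1) + t.data.shape)


def _check_same_shape(a: Tensor, b: Tensor) -> None:
    if a.data.shape != b.data.shape:
        raise ShapeError(f"shape mismatch: {a.data.shape} vs {b.data.shape}")


def mse_loss(pred, target) -> Tensor:
    """Mean of squared pixel differences over all pixels and batch items."""
    p, t = _as_batch(pred), _as_batch(target)
    _check_same_shape(p, t)
    d = p - t
    return ad.mean(d * d)


def gaussian_window(size: int, sigma: float) -> np.ndarray:
    """Normalized 2-D Gaussian window used for local image statistics."""
    r = np.arange(size, dtype=np.float64) - (size - 1) / 2.0
    g = np.exp(-(r**2) / (2.0 * sigma**2))
    w = np.outer(g, g)
    return w / w.sum()


def _local_stats(x: Tensor, y: Tensor, win: Tensor):
    """Gaussian-windowed means, variances and covariance (valid region)."""
    mu_x = ad.conv2d(x, win)
    mu_y = ad.conv2d(y, win)
    sxx = ad.conv2d(x * x, win) - mu_x * mu_x
    syy = ad.conv2d(y * y, win) - mu_y * mu_y
    sxy = ad.conv2d(x * y, win) - mu_x * mu_y
    return mu_x, mu_y, sxx, syy, sxy


def ms_ssim_loss(pred, target, params: MsSsimParams | None = None) -> Tensor:
    """1 - MS-SSIM(pred, target).

    MS-SSIM combines the mean luminance term at the coarsest scale with the
    product over scales of the mean contrast-structure terms, each raised to
    its per-scale exponent; scales are linked by 2x2 average pooling.
    Negative contrast-structure values (possible when the prediction is far
    from the target, e.g. early in training) are rectified pixelwise and the
    spatial means floored at 1e-6 before exponentiation so the fractional
    powers and their gradients stay finite; for similar images in [0, 1]
    both guards are inactive.
    """
    p = params.validate() if params is not None else MsSsimParams()
    x, y = _as_batch(pred), _as_batch(target)
    _check_same_shape(x, y)
    min_side = min(x.data.shape[2], x.data.shape[3])
    needed = p.window_size * 2 ** (p.n_scales - 1)
    if min_side < needed:
        max_m = int(np.floor(np.log2(min_side / p.window_size))) + 1
        raise ConfigurationError(
            f"images of side {min_side} are too small for {p.n_scales} scales "
            f"with an {p.window_size}-pixel window; reduce n_scales to "
            f"{max(max_m, 1)} or fewer"
        )
    win = Tensor(gaussian_window(p.window_size, p.window_sigma)[None, None])
    weights = p.effective_weights()
    result = None
    floor = 1e-6
    for j in range(p.n_scales):
        mu_x, mu_y, sxx, syy, sxy = _local_stats(x, y, win)
        cs_map = ad.relu((2.0 * sxy + p.c2) / (sxx + syy + p.c2))
        cs = ad.clamp_min(ad.mean(cs_map), floor) ** float(weights[j])
        if j < p.n_scales - 1:
            term = cs
            x, y = ad.avg_pool2d(x), ad.avg_pool2d(y)
        else:
            l_map = (2.0 * mu_x * mu_y + p.c1) / (mu_x * mu_x + mu_y * mu_y + p.c1)
            term = (ad.clamp_min(ad.mean(l_map), floor) ** float(weights[j])) * cs
        result = term if result is None else result * term
    return 1.0 - result


def gradient_loss(pred, target, kernel: GradientKernel | None = None) -> Tensor:
    """MSE between high-pass filtered prediction and target.

    Both images are cross-correlated with the fixed 3x3 kernel (valid
    region, no padding) and the mean squared difference of the two response
    maps is returned.
    """
    k = (kernel if kernel is not None else GradientKernel()).validate()
    p, t = _as_batch(pred), _as_batch(target)
    _check_same_shape(p, t)
    if min(p.data.shape[2], p.data.shape[3]) < k.kernel.shape[0]:
        raise ShapeError("images smaller than the gradient kernel")
    kt = Tensor(k.kernel[None, None])
    gp = ad.conv2d(p, kt)
    gt = ad.conv2d(t, kt)
    d = gp - gt
    return ad.mean(d * d)


def composite_loss(
    pred,
    target,
    weights: LossWeights | None = None,
    ms_params: MsSsimParams | None = None,
    kernel: GradientKernel | None = None,
) -> tuple[Tensor, dict]:
    """Weighted sum of the three losses plus an unweighted per-term breakdown."""
    w = (weights if weights is not None else LossWeights()).validate()
    t_mse = mse_loss(pred, target)
    terms = {"mse": t_mse.item()}
    loss = w.lambda1 * t_mse
    if w.lambda2 != 0.0:
        t_ms = ms_ssim_loss(pred, target, ms_params)
        terms["ms_ssim"] = t_ms.item()
        loss = loss + w.lambda2 * t_ms
    else:
        terms["ms_ssim"] = 0.0
    if w.lambda3 != 0.0:
        t_gr = gradient_loss(pred, target, kernel)
        terms["gradient"] = t_gr.item()
        loss = loss + w.lambda3 * t_gr
    else:
        terms["gradient"] = 0.0
    return loss, terms


def total_loss(original, correction):
    """Sum of the original-pass and correction-pass losses."""
    for name, v in (("original", original), ("correction", correction)):
        val = v.item() if isinstance(v, Tensor) else float(v)
        if not np.isfinite(val):
            raise NumericError(f"{name} loss is not finite: {val}")
    if isinstance(original, Tensor) or isinstance(correction, Tensor):
        return ad.as_tensor(original) + ad.as_tensor(correction)
    return original + correction
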