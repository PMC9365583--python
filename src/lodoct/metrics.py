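"""Evaluation metrics: PSNR and single-scale SSIM, plus dataset evaluation.

PSNR = 10 * log10(MAX^2 / MSE) in decibels. SSIM is the mean of the local
structural-similarity map computed with an 11x11 Gaussian window
(sigma = 1.5) over the valid region, with stability constants
c1 = (0.01 * MAX)^2 and c2 = (0.03 * MAX)^2. MAX defaults to 1.0, the
dynamic range of normalized slices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .errors import ConfigurationError, ShapeError
from .losses import gaussian_window

__all__ = ["MetricResult", "psnr", "ssim", "evaluate"]


@dataclass
class MetricResult:
    psnr: float
    ssim: float
    max_value: float
    n_images: int


def _check_pair(x, y):
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ShapeError(f"shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def psnr(x, y, max_value: float = 1.0, zero_mse_value: float = np.inf) -> float:
    """Peak signal-to-noise ratio in dB; ``zero_mse_value`` for identical images."""
    if max_value <= 0:
        raise ConfigurationError("max_value must be > 0")
    x, y = _check_pair(x, y)
    mse = float(np.mean((x - y) ** 2))
    if mse == 0.0:
        return zero_mse_value
    return 10.0 * np.log10(max_value**2 / mse)


def _window_corr(img: np.ndarray, win: np.ndarray) -> np.ndarray:
    # symmetric window, so correlation == convolution
    return fftconvolve(img, win, mode="valid")


def ssim(
    x,
    y,
    max_value: float = 1.0,
    window_size: int = 11,
    window_sigma: float = 1.5,
) -> float:
    """Mean local SSIM over the valid sliding-window region."""
    if max_value <= 0:
        raise ConfigurationError("max_value must be > 0")
    x, y = _check_pair(x, y)
    if min(x.shape) < window_size:
        raise ConfigurationError(
            f"image of shape {x.shape} is smaller than the {window_size}-pixel window"
        )
    win = gaussian_window(window_size, window_sigma)
    c1 = (0.01 * max_value) ** 2
    c2 = (0.03 * max_value) ** 2
    mu_x = _window_corr(x, win)
    mu_y = _window_corr(y, win)
    sxx = _window_corr(x * x, win) - mu_x**2
    syy = _window_corr(y * y, win) - mu_y**2
    sxy = _window_corr(x * y, win) - mu_x * mu_y
    num = (2 * mu_x * mu_y + c1) * (2 * sxy + c2)
    den = (mu_x**2 + mu_y**2 + c1) * (sxx + syy + c2)
    return float(np.mean(num / den))


def evaluate(model, dataset, max_value: float = 1.0, csv_path=None) -> pd.DataFrame:
    """Per-image and mean PSNR/SSIM for LDCT-vs-NDCT and denoised-vs-NDCT.

    ``dataset`` is a sequence of :class:`~lodoct.data_sim.ImagePair`. The
    returned frame has one row per image plus a trailing ``mean`` row; with
    ``csv_path`` it is also written as CSV.
    """
    pairs = list(dataset)
    if not pairs:
        raise ConfigurationError("evaluate requires a non-empty dataset")
    rows = []
    for i, pair in enumerate(pairs):
        den = model.denoise(pair.ldct)
        rows.append(
            {
                "image": i,
                "psnr_ldct": psnr(pair.ldct, pair.ndct, max_value),
                "ssim_ldct": ssim(pair.ldct, pair.ndct, max_value),
                "psnr_denoised": psnr(den, pair.ndct, max_value),
                "ssim_denoised": ssim(den, pair.ndct, max_value),
            }
        )
    frame = pd.DataFrame(rows)
    mean_row = frame.drop(columns="image").mean().to_dict()
    mean_row["image"] = "mean"
    frame = pd.concat([frame, pd.DataFrame([mean_row])], ignore_index=True)
    if csv_path is not None:
        frame.to_csv(csv_path, index=False)
    return frame
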