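"""Brute-force reference implementations, written independently of the
package's vectorized code paths.

Everything here computes local statistics by explicit sliding-window sums
and builds multi-scale quantities scale by scale, so agreement with the
package is a genuine dual-route check rather than a re-run of the same code.
"""

import numpy as np


def mse_ref(a, b):
    diff = np.asarray(a, dtype=float).ravel() - np.asarray(b, dtype=float).ravel()
    return float(sum(d * d for d in diff) / diff.size)


def psnr_ref(a, b, max_value=1.0):
    mse = mse_ref(a, b)
    return float("inf") if mse == 0 else 10.0 * np.log10(max_value**2 / mse)


def corr2d_valid_ref(img, kernel):
    """Plain double-loop valid cross-correlation."""
    img = np.asarray(img, dtype=float)
    k = np.asarray(kernel, dtype=float)
    kh, kw = k.shape
    ho, wo = img.shape[0] - kh + 1, img.shape[1] - kw + 1
    out = np.empty((ho, wo))
    for i in range(ho):
        for j in range(wo):
            out[i, j] = float((img[i : i + kh, j : j + kw] * k).sum())
    return out


def gradient_loss_ref(pred, target, kernel):
    gp = corr2d_valid_ref(pred, kernel)
    gt = corr2d_valid_ref(target, kernel)
    return mse_ref(gp, gt)


def gaussian_window_ref(size, sigma):
    w = np.empty((size, size))
    c = (size - 1) / 2.0
    for i in range(size):
        for j in range(size):
            w[i, j] = np.exp(-((i - c) ** 2 + (j - c) ** 2) / (2 * sigma**2))
    return w / w.sum()


def _windowed_stats_ref(x, y, win):
    """Per-position weighted mean/variance/covariance over valid windows."""
    size = win.shape[0]
    ho, wo = x.shape[0] - size + 1, x.shape[1] - size + 1
    mu_x = np.empty((ho, wo))
    mu_y = np.empty((ho, wo))
    var_x = np.empty((ho, wo))
    var_y = np.empty((ho, wo))
    cov = np.empty((ho, wo))
    for i in range(ho):
        for j in range(wo):
            px = x[i : i + size, j : j + size]
            py = y[i : i + size, j : j + size]
            mx = (win * px).sum()
            my = (win * py).sum()
            mu_x[i, j] = mx
            mu_y[i, j] = my
            var_x[i, j] = (win * px * px).sum() - mx * mx
            var_y[i, j] = (win * py * py).sum() - my * my
            cov[i, j] = (win * px * py).sum() - mx * my
    return mu_x, mu_y, var_x, var_y, cov


def ssim_ref(x, y, max_value=1.0, window_size=11, sigma=1.5):
    """Mean single-scale SSIM over the valid sliding-window region."""
    win = gaussian_window_ref(window_size, sigma)
    c1 = (0.01 * max_value) ** 2
    c2 = (0.03 * max_value) ** 2
    mu_x, mu_y, var_x, var_y, cov = _windowed_stats_ref(
        np.asarray(x, float), np.asarray(y, float), win
    )
    num = (2 * mu_x * mu_y + c1) * (2 * cov + c2)
    den = (mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2)
    return float((num / den).mean())


def _downsample2_ref(x):
    h, w = x.shape[0] // 2 * 2, x.shape[1] // 2 * 2
    x = x[:h, :w]
    return (x[0::2, 0::2] + x[0::2, 1::2] + x[1::2, 0::2] + x[1::2, 1::2]) / 4.0


def ms_ssim_ref(x, y, n_scales, scale_weights, max_value=1.0, window_size=11, sigma=1.5):
    """Per-scale MS-SSIM built from the separate luminance, contrast and
    structure terms (c3 = c2/2), rectified pixelwise and floored at 1e-6."""
    x = np.asarray(x, float).copy()
    y = np.asarray(y, float).copy()
    win = gaussian_window_ref(window_size, sigma)
    c1 = (0.01 * max_value) ** 2
    c2 = (0.03 * max_value) ** 2
    c3 = c2 / 2.0
    weights = np.asarray(scale_weights[:n_scales], float)
    if n_scales < len(scale_weights):
        weights = weights / weights.sum()
    msssim = 1.0
    for j in range(n_scales):
        mu_x, mu_y, var_x, var_y, cov = _windowed_stats_ref(x, y, win)
        sd_x = np.sqrt(np.maximum(var_x, 0.0))
        sd_y = np.sqrt(np.maximum(var_y, 0.0))
        contrast = (2 * sd_x * sd_y + c2) / (var_x + var_y + c2)
        structure = (cov + c3) / (sd_x * sd_y + c3)
        cs = np.maximum(contrast * structure, 0.0)
        if j == n_scales - 1:
            lum = (2 * mu_x * mu_y + c1) / (mu_x**2 + mu_y**2 + c1)
            msssim *= max(lum.mean(), 1e-6) ** weights[j]
        msssim *= max(cs.mean(), 1e-6) ** weights[j]
        if j < n_scales - 1:
            x, y = _downsample2_ref(x), _downsample2_ref(y)
    return float(msssim)


def ms_ssim_loss_ref(x, y, n_scales, scale_weights, **kw):
    return 1.0 - ms_ssim_ref(x, y, n_scales, scale_weights, **kw)
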