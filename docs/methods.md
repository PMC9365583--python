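# Methods

This note documents the models and procedures the package implements, the
defaults and their rationale, the numerical choices, and the limits of what
the synthetic experiments show.

## Problem setting

Supervised low-dose CT denoising: given registered pairs (L, N) of a
low-dose slice and its normal-dose counterpart on a common normalized
intensity scale in [0, 1], learn f(L) ≈ N. The package trains and evaluates
entirely on synthetic pairs by default; a DICOM path exists for real paired
series but is optional and untested against clinical data.

## Network

The denoiser is an encoder/decoder built from densely connected blocks and
stride-1 deconvolutions. Defaults (full scale): stem 7×7 conv to 16
channels; 4 levels; per level a 2×2 max-pool then an improved residual
dense block; per decoder level a nearest-neighbour ×2 upsample,
concatenation with the same-resolution encoder feature, a 5×5 deconvolution
to 32 channels and a 1×1 deconvolution to 16, each followed by ReLU then
batch normalization; a 1×1 single-channel head with no activation. Weights
are initialized from a zero-mean Gaussian with variance 0.01 (std 0.1),
biases zero, batch-norm scale 1 / shift 0.

### IRDB wiring

The improved residual dense block is specified here as:

    input (C ch)
      → dense chain: D layers of 3×3 conv + ReLU, growth G, each consuming
        the concatenation of the input and all previous outputs (no batch
        norm inside the chain)
      → 1×1 "local fusion" conv widening to the bottleneck width B + ReLU
      → enhanced residual sub-block: x + conv3×3(ReLU(conv3×3(x))) at width B
      → 1×1 projection back to C
      → + identity skip from the block input.

Defaults C = G = 16, D = 4, B = 80 = C + D·G: the fusion layer consumes the
80-channel concatenation and the block's published channel tags (80-channel
1×1, 16-channel 3×3 and 1×1 convolutions) are all realized. The exact
ordering of fusion, residual sub-block and projection is not uniquely
determined by the block's published diagram; this package fixes the order
above and treats it as its own design choice. With `use_irdb=False` the
enhanced-residual sub-block and the identity skip are removed, leaving the
plain dense block of the original DD-Net (the ablation toggle).

"Deconvolution" means stride-1 transposed convolution: spatial size is
preserved and all upsampling is done by the dedicated ×2 layers (the
architecture lists them separately, so deconvolutions cannot also
upsample). Nearest-neighbour upsampling is used as the cheapest
deterministic choice. Skip features are concatenated *before* the first
deconvolution of each decoder level.

Input sides must be divisible by 2^levels (16 at full scale); violations
raise a shape error naming the divisor. The same code path builds the full
model (~691k parameters) and the two-level test model (~27k parameters).

## Losses

Composite loss L = λ₁·L_MSE + λ₂·L_MS-SSIM + λ₃·L_grad with defaults
(1, 0.15, 0.8).

* **MSE** — mean squared pixel difference over batch and pixels.
* **MS-SSIM loss** — 1 − MS-SSIM. Local statistics use an 11×11 Gaussian
  window, σ = 1.5, valid region only; scales are linked by 2×2 average
  pooling; stability constants C1 = (0.01·R)², C2 = (0.03·R)², C3 = C2/2
  with dynamic range R = 1 on the normalized scale. Per-scale exponents
  (luminance = contrast = structure) default to the conventional five-scale
  values (0.0448, 0.2856, 0.3001, 0.2363, 0.1333); they are used as printed
  even though they sum to 1.0001. Five scales need ≥ 176-pixel sides, so
  `n_scales` is configurable down to 1; with fewer scales the leading
  weights are renormalized to sum to one (64-pixel training uses 3 scales).
* **Gradient loss** — both images are cross-correlated (valid region, no
  padding, no kernel flip — the deep-learning convolution convention) with
  the fixed zero-sum kernel [[−1,−1,−1],[0,0,0],[1,1,1]] and the MSE of the
  two response maps is returned. Zero response on constants, invariant to a
  global intensity shift applied to both images.

Numerical guards in the MS-SSIM loss: the contrast-structure map is
rectified pixelwise and the spatial means are floored at 1e-6 before the
fractional exponentiation. Without the floor the exponent's gradient is
infinite exactly at zero, which occurs when the prediction is still far
from the target (observed in the first epoch of training). Both guards are
inactive for similar images in [0, 1], and the tests' brute-force oracle
applies the same rectification.

The mechanism's total is L_total = L_original + L_correction, a plain sum.

## Mask-guided correction training

Per step: I₁ = f(L₁); D₁ = N₁ − I₁; mask = 𝟙[|D₁| > t]; L₂ = L₁⊙mask,
N₂ = N₁⊙mask; I₂ = f(L₂); minimize L(I₁,N₁) + L(I₂,N₂) in one optimizer
update with gradients through both passes.

Choices where the procedure is underdetermined:

* The threshold applies to the **absolute** difference; both over- and
  under-estimated regions count as poorly restored. Ties (|d| = t) are
  filtered, making t = 0 well defined on exactly-zero pixels.
* The mask is recomputed from the current model every step and treated as a
  constant under differentiation (thresholding is non-differentiable).
* Batch-norm statistics update only on the first pass; the second pass
  reuses the first pass's batch moments, frozen and treated as constants.
  This keeps one update per step and makes the all-pass identity exact: in
  evaluation mode with t = 0 the correction pass sees bit-identical input,
  so I₂ == I₁ and L_total = 2·L_original.
* The correction losses (including MS-SSIM and gradient terms) are computed
  over the **full** masked images, zeros included, not only retained pixels.
* Epoch accounting: the 160 mechanism epochs *follow* the 80 pretraining
  epochs, and the learning-rate drop epoch (130) counts within the
  mechanism phase. Both readings of the schedule are representable via
  `MechanismConfig` / `TrainConfig`.

Threshold selection: `threshold_scan` reports the retained-pixel fraction
per threshold over a dataset (monotone non-increasing in t);
`suggest_threshold` proposes the smallest scanned threshold whose retained
fraction falls in a configurable band, default 5–20% — a quantitative proxy
for "filter most flat areas, keep the subtle structures". The default scan
grid is {0.01, 0.04, 0.07, 0.10}. The final choice stays with the user.

## Optimization

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8), batch size 8, lr 1e-4 dropping to
5e-5 at mechanism epoch 130 (full scale). Shuffling is seeded per epoch
from the run seed, so a run is a pure function of its `RunConfig` on one
device; two identical runs produce identical epoch-loss logs.

## Compute backend

No GPU framework is used: `lodoct.autodiff` is a small reverse-mode
autodiff engine over float64 NumPy arrays (im2col convolutions, analytic
batch-norm backward, argmax-routed max-pool gradients), and `lodoct.nn`
provides the layers and Adam. Every primitive's gradient is verified
against central finite differences in the test suite. Double precision
costs speed but buys bit-exact reproducibility and clean agreement with the
brute-force oracles.

## Synthetic data

`generate_phantom` draws n random ellipses (default 6) with centres within
±0.22 of the image side around the centre, semi-axes 5–18% of the side,
additive intensities U(0.1, 0.5) on a 0.1 background, clipped to [0, 1] and
blurred with a Gaussian of σ = 1 px (`edge_softness`). The blur emulates
partial-volume/finite-focal-spot softening and keeps filtered
backprojection accurate at small image sizes: with 128 angles on 64-pixel
phantoms the noise-free reconstruction stays above ~41 dB PSNR, isolating
photon noise as the dominant LDCT degradation.

`simulate_pair` scales line integrals so a full-intensity path across the
image attenuates by `max_attenuation` = 4 e-folds (a body-scale value),
draws transmitted counts ~ Poisson(N₀·dose·e^(−p)) per bin, floors them at
one count (standard practice; avoids log(0)), log-transforms and
reconstructs with a ramp filter. `incident_photons` defaults to N₀ = 3000
per bin at full dose so that 10%-dose pairs land near 22 dB PSNR —
comparable to clinical chest LDCT quality — with 25%-dose pairs near 27 dB.
The normal-dose image is the clean phantom (exact ground truth for metric
tests); `ndct_from_projection` switches to a noise-free full-dose
reconstruction instead. Both images are renormalized to [0, 1] by the NDCT
min/max (one shared affine map per pair), so a single mask threshold is
meaningful across the pair.

What the simulator does **not** emulate: beam hardening, scatter, detector
cross-talk, helical/cone-beam geometry, vendor reconstruction kernels,
anatomical texture, or 3-D context. Passing tests therefore demonstrate
correctness of the training machinery and the qualitative low-dose physics,
not clinical denoising performance; the headline PSNR/SSIM values of
clinical studies are not reproducible from this package without the real
paired data.

## Metrics

PSNR = 10·log10(MAX²/MSE) with MAX defaulting to 1.0 on the normalized
scale (configurable; identical images return a configurable cap, default
+∞). SSIM for evaluation is single-scale, same 11×11/σ1.5 Gaussian window
and valid-region mean as the loss's statistics, c1 = (0.01·MAX)²,
c2 = (0.03·MAX)². Both agree with brute-force sliding-window oracles to
1e-6 and (for SSIM) with scikit-image's Gaussian-weighted implementation up
to its different border handling.

## Problem sizes used by the tests and the acceptance script

The suite and `scripts/acceptance.py` run on 64-pixel slices, 128
projection angles, a two-level ~27k-parameter model, 40 training + 8
held-out pairs at 10% dose, and a 5 + 10 epoch schedule at lr 1e-3 halving
at mechanism epoch 8 (the full-scale schedule scaled by roughly its own
ratios). These sizes are the package's desk-scale study conditions: large
enough for the held-out denoised-vs-LDCT PSNR comparison to come out
positive at the tested seeds (~+3 dB), small enough to run in about a
minute on one CPU. At this scale the gain fluctuates by a few dB across
seeds; stabilizing it would need more data and epochs, not different code.

## Known limitations

* Training is CPU-bound NumPy; full-scale 512×512 training is out of reach
  here (the code builds the full model, but a realistic schedule would take
  days).
* The enhanced-residual sub-block is a minimal two-convolution residual
  unit; the attention components of its namesake are intentionally omitted.
* DICOM support is read-only and untested against the clinical archive it
  targets; metric scales on HU-valued data depend on a windowing choice the
  user must make explicitly.
* The MS-SSIM evaluation of image quality is computed on [0, 1]-normalized
  images; published clinical PSNR/SSIM values depend on undocumented
  normalization choices and are not comparable.
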