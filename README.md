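# lodoct

Low-dose CT (LDCT) image denoising with an improved DD-Net and a
mask-guided correction-loss training mechanism, plus a synthetic
paired-slice simulator so the whole pipeline runs at desk scale with no
external data.

Reducing the X-ray dose of a CT scan protects the patient but floods the
reconstruction with noise and streak artifacts that can obscure subtle
structures. Supervised denoisers learn the mapping from a low-dose slice to
its registered normal-dose (NDCT) counterpart. This package is aimed at
medical-image-analysis researchers who want a compact, fully tested
reference implementation of that training recipe — network, losses,
mechanism, metrics and simulator — usable from Python or a thin CLI.

## The model

**Network.** An encoder/decoder ("improved DD-Net"): a 7×7 stem convolution
(16 channels), then per encoder level a 2×2 max-pool followed by an
*improved residual dense block* (IRDB) — a densely connected chain of 3×3
convolutions (growth 16, no batch norm), a 1×1 local fusion to an 80-channel
bottleneck, an enhanced-residual sub-block, a 1×1 projection back to the
block width, and an identity skip. Each decoder level upsamples ×2,
concatenates the same-scale encoder feature, and applies two stride-1
deconvolutions (5×5 → 32 ch, 1×1 → 16 ch), each with ReLU and batch norm; a
1×1 head emits the denoised slice. Four levels at full scale: 1 stem conv,
4 max-pools, 4 IRDBs, 4 upsamplings, 8 deconvolutions, 1×1 head.

**Loss.** With prediction *I* and target *N*,

    L = λ₁·L_MSE + λ₂·(1 − MS-SSIM(I, N)) + λ₃·L_grad,   (λ₁, λ₂, λ₃) = (1, 0.15, 0.8)

where MS-SSIM uses the standard five-scale exponents
(0.0448, 0.2856, 0.3001, 0.2363, 0.1333) with an 11×11 Gaussian window
(σ = 1.5), and L_grad is the MSE between both images filtered with the fixed
high-pass kernel K = [[−1,−1,−1],[0,0,0],[1,1,1]].

**Mechanism.** Each training step runs the network twice:

1. denoise L₁ → I₁, compute the original loss L(I₁, N₁);
2. threshold |N₁ − I₁| into a binary mask (1 = poorly restored pixel,
   threshold 0.04 on the normalized scale for chest-like data, 0.004 for
   head-like data);
3. filter both inputs elementwise: L₂ = L₁⊙mask, N₂ = N₁⊙mask;
4. denoise L₂ → I₂ and add the correction loss: L_total = L(I₁,N₁) + L(I₂,N₂).

Training is two-phase: pretraining without the mechanism (80 epochs at full
scale), then the mechanism phase (160 epochs), Adam(0.9, 0.999), batch 8,
lr 1e-4 halving at mechanism epoch 130, Gaussian init (variance 0.01). The
network and its training run on the package's own NumPy reverse-mode
autodiff backend (`lodoct.autodiff` / `lodoct.nn`), verified against finite
differences in the test suite.

**Simulator.** Random-ellipse phantoms are forward projected, transmitted
counts are drawn as Poisson(N₀ · dose · e^(−p)) per detector bin, and the
low-dose slice is a ramp-filtered backprojection of the log-transformed
counts — reproducing the grainy noise and streaks of photon starvation. The
clean phantom is the normal-dose ground truth.

## Worked example

`python examples/01_simulate_pairs.py` — dose response of the simulator:

```
dose 100%: PSNR(ldct, ndct) = 33.31 dB, SSIM = 0.577
dose  25%: PSNR(ldct, ndct) = 27.50 dB, SSIM = 0.331
dose  10%: PSNR(ldct, ndct) = 23.68 dB, SSIM = 0.233
noise-free reconstruction: PSNR = 43.86 dB (pure FBP discretization error)
```

Lower dose → fewer photons → lower pair PSNR; the noise-free line isolates
the reconstruction error itself.

`python examples/04_train_and_evaluate.py` — a ~1-minute end-to-end run
(two-level model, ~27k parameters, 40 synthetic 10%-dose pairs, 5
pretraining + 10 mechanism epochs):

```
 epoch     phase     lr  loss_total
     1  pretrain 0.0010    0.332688
     ...
    15 mechanism 0.0005    0.100801

held-out LDCT     PSNR 21.58 dB, SSIM 0.290
held-out denoised PSNR 24.86 dB, SSIM 0.419
PSNR gain +3.28 dB
```

The trained model beats the raw low-dose input on held-out pairs by ~3 dB;
at this miniature scale the margin varies by a few dB across seeds. The
other examples show the loss breakdown, a single mechanism step, and the
threshold-selection scan (retained-pixel fraction per threshold).

A CLI mirrors the library: `lodoct simulate | describe | train |
threshold-scan | evaluate | denoise` (see `--help`).

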