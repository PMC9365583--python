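"""Mask-guided correction-loss training (the "local filtered mechanism").

One mechanism step runs the denoiser twice. The low-dose slice L1 is
denoised to I1 and the original loss against the normal-dose slice N1 is
computed. The difference image D1 = N1 - I1 is thresholded on its absolute
value into a binary mask (1 = poorly restored pixel, kept; 0 = well
restored, filtered out), the mask multiplies both L1 and N1, the filtered
low-dose image is denoised to I2, and the correction loss between I2 and the
filtered N2 is added. The mask is recomputed from the current model every
step and treated as a constant under differentiation (thresholding is not
differentiable); both passes feed a single optimizer update.

Training is two-phase: a pretraining phase minimizing the original loss
alone (80 epochs at full scale), then a mechanism phase minimizing the
summed loss (160 epochs), with the learning rate dropping at epoch 130 of
the mechanism phase. Batch-normalization statistics update only on the
first pass of each step; the second pass reuses them frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Tensor
from .errors import ConfigurationError, ShapeError
from .losses import GradientKernel, LossWeights, MsSsimParams, composite_loss
from .metrics import psnr, ssim
from .nn import Adam, frozen_batch_stats

__all__ = [
    "MechanismConfig",
    "MaskImage",
    "MechanismStepResult",
    "difference_image",
    "make_mask",
    "apply_mask",
    "mechanism_step",
    "train",
    "threshold_scan",
    "suggest_threshold",
]


@dataclass
class MechanismConfig:
    """Mechanism parameters.

    The threshold lives on the normalized [0, 1] intensity scale; 0.04 is
    the chest-data choice, 0.004 the head-data one. Epoch counts are the
    full-scale schedule; scaled-down runs override them.
    """

    threshold: float = 0.04
    enabled: bool = True
    pretrain_epochs: int = 80
    mechanism_epochs: int = 160

    def validate(self) -> "MechanismConfig":
        if self.threshold < 0:
            raise ConfigurationError(f"threshold must be >= 0, got {self.threshold}")
        if self.pretrain_epochs < 0 or self.mechanism_epochs < 0:
            raise ConfigurationError("epoch counts must be >= 0")
        return self


@dataclass
class MaskImage:
    """Binary per-pixel map; 1 marks pixels preserved for the correction pass."""

    mask: np.ndarray

    def validate(self) -> "MaskImage":
        values = np.unique(self.mask)
        if not np.all(np.isin(values, (0.0, 1.0))):
            raise ConfigurationError("mask values must be 0 or 1")
        return self

    @property
    def retained_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass
class MechanismStepResult:
    denoised: np.ndarray  # I1
    difference: np.ndarray  # D1 = N1 - I1
    mask: MaskImage
    filtered_ldct: np.ndarray  # L2
    filtered_ndct: np.ndarray  # N2
    filtered_denoised: np.ndarray  # I2
    original_loss: float
    correction_loss: float
    total: float
    original_terms: dict = field(default_factory=dict)
    correction_terms: dict = field(default_factory=dict)
    loss_graph: Tensor | None = None  # total loss tensor for backprop


def difference_image(ndct: np.ndarray, denoised: np.ndarray) -> np.ndarray:
    """Pixelwise NDCT minus prediction."""
    ndct = np.asarray(ndct, dtype=np.float64)
    denoised = np.asarray(denoised, dtype=np.float64)
    if ndct.shape != denoised.shape:
        raise ShapeError(f"shape mismatch: {ndct.shape} vs {denoised.shape}")
    return ndct - denoised


def make_mask(diff: np.ndarray, threshold: float) -> MaskImage:
    """Retain pixels where |difference| strictly exceeds the threshold."""
    if threshold < 0:
        raise ConfigurationError(f"threshold must be >= 0, got {threshold}")
    return MaskImage(mask=(np.abs(np.asarray(diff)) > threshold).astype(np.float64))


def apply_mask(image: np.ndarray, mask: MaskImage) -> np.ndarray:
    """Elementwise product; filtered pixels become exactly zero."""
    image = np.asarray(image, dtype=np.float64)
    if image.shape != mask.mask.shape:
        raise ShapeError(f"shape mismatch: {image.shape} vs {mask.mask.shape}")
    return image * mask.mask


def _stack(pairs) -> tuple[np.ndarray, np.ndarray]:
    """Stack ImagePairs (or one pair) into (N, 1, H, W) arrays."""
    if not isinstance(pairs, (list, tuple)):
        pairs = [pairs]
    ldct = np.stack([p.ldct for p in pairs])[:, None]
    ndct = np.stack([p.ndct for p in pairs])[:, None]
    return ldct, ndct


def mechanism_step(
    model,
    pairs,
    cfg: MechanismConfig | None = None,
    weights: LossWeights | None = None,
    ms_params: MsSsimParams | None = None,
    kernel: GradientKernel | None = None,
) -> MechanismStepResult:
    """Run the full two-pass procedure on a pair or batch of pairs.

    Returns all intermediate images plus the scalar losses; when the model
    is in training mode the returned ``loss_graph`` tensor carries gradients
    through both passes for a single optimizer update.
    """
    cfg = (cfg if cfg is not None else MechanismConfig()).validate()
    l1, n1 = _stack(pairs)
    i1 = model(l1)
    original, orig_terms = composite_loss(i1, n1, weights, ms_params, kernel)
    d1 = difference_image(n1, i1.data)
    mask = make_mask(d1, cfg.threshold)
    l2 = apply_mask(l1, mask)
    n2 = apply_mask(n1, mask)
    with frozen_batch_stats(model):
        i2 = model(l2)
    correction, corr_terms = composite_loss(i2, n2, weights, ms_params, kernel)
    loss = original + correction
    return MechanismStepResult(
        denoised=i1.data[:, 0],
        difference=d1[:, 0],
        mask=MaskImage(mask.mask[:, 0]),
        filtered_ldct=l2[:, 0],
        filtered_ndct=n2[:, 0],
        filtered_denoised=i2.data[:, 0],
        original_loss=original.item(),
        correction_loss=correction.item(),
        total=loss.item(),
        original_terms=orig_terms,
        correction_terms=corr_terms,
        loss_graph=loss,
    )


def _epoch_seed(seed: int, epoch: int) -> int:
    return int(np.random.SeedSequence([seed, epoch]).generate_state(1)[0])


def train(model, dataset, run_cfg, val_dataset=None, out_dir=None):
    """Two-phase training; returns the model and a per-epoch log frame.

    Phase 1 minimizes the composite loss of the plain denoising pass for
    ``mechanism.pretrain_epochs`` epochs; phase 2 adds the correction loss
    for ``mechanism.mechanism_epochs`` epochs (with the mechanism disabled
    it degenerates to continued phase-1 training). Fully deterministic for
    a fixed ``run_cfg`` on one device. With ``out_dir`` set, writes
    ``training_log.csv`` and a final checkpoint.
    """
    from .data_io import batch_pairs  # deferred: data_io imports this module

    run_cfg.validate()
    dataset = list(dataset)
    if not dataset:
        raise ConfigurationError("training requires a non-empty dataset")
    mech = run_cfg.mechanism
    trainer = run_cfg.trainer
    optimizer = Adam(
        model.parameters(),
        lr=trainer.learning_rate,
        betas=(trainer.beta1, trainer.beta2),
    )
    model.train()
    records = []
    global_epoch = 0
    schedule = [("pretrain", mech.pretrain_epochs), ("mechanism", mech.mechanism_epochs)]
    for phase, n_epochs in schedule:
        for phase_epoch in range(1, n_epochs + 1):
            global_epoch += 1
            if phase == "mechanism" and phase_epoch == trainer.lr_drop_epoch:
                optimizer.lr = trainer.lr_after_drop
            use_mechanism = phase == "mechanism" and mech.enabled
            batches = batch_pairs(
                dataset, trainer.batch_size, _epoch_seed(run_cfg.seed, global_epoch)
            )
            sums = {"total": 0.0, "original": 0.0, "correction": 0.0,
                    "mse": 0.0, "ms_ssim": 0.0, "gradient": 0.0}
            for batch in batches:
                optimizer.zero_grad()
                if use_mechanism:
                    step = mechanism_step(
                        model, batch, mech, run_cfg.loss_weights, run_cfg.ms_ssim
                    )
                    loss = step.loss_graph
                    sums["original"] += step.original_loss
                    sums["correction"] += step.correction_loss
                    terms = step.original_terms
                else:
                    l1, n1 = _stack(batch)
                    loss, terms = composite_loss(
                        model(l1), n1, run_cfg.loss_weights, run_cfg.ms_ssim
                    )
                    sums["original"] += loss.item()
                if not np.isfinite(loss.item()):
                    raise ArithmeticError(
                        f"non-finite loss at epoch {global_epoch}: {loss.item()}"
                    )
                loss.backward()
                optimizer.step()
                sums["total"] += loss.item()
                for key in ("mse", "ms_ssim", "gradient"):
                    sums[key] += terms[key]
            n = max(len(batches), 1)
            record = {
                "epoch": global_epoch,
                "phase": phase,
                "lr": optimizer.lr,
                "loss_total": sums["total"] / n,
                "loss_original": sums["original"] / n,
                "loss_correction": sums["correction"] / n,
                "loss_mse": sums["mse"] / n,
                "loss_ms_ssim": sums["ms_ssim"] / n,
                "loss_gradient": sums["gradient"] / n,
            }
            if val_dataset:
                record.update(_validate(model, val_dataset))
                model.train()
            records.append(record)
    log = pd.DataFrame(records)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        log.to_csv(out_dir / "training_log.csv", index=False)
        from .network import save_checkpoint

        save_checkpoint(out_dir / "model.ckpt", model)
    return model, log


def _validate(model, pairs) -> dict:
    model.eval()
    ps, ss = [], []
    for pair in pairs:
        den = model.denoise(pair.ldct)
        ps.append(psnr(den, pair.ndct))
        ss.append(ssim(den, pair.ndct))
    return {"val_psnr": float(np.mean(ps)), "val_ssim": float(np.mean(ss))}


def threshold_scan(model, dataset, thresholds, dump_dir=None) -> pd.DataFrame:
    """Retained-pixel statistics over a threshold grid.

    For each threshold, reports the fraction of pixels the mask retains
    across the whole dataset plus per-image mean/std. Retention is monotone
    non-increasing in the threshold. With ``dump_dir`` set, writes the
    difference image, mask and filtered pair for the first dataset item at
    each threshold (16-bit PNG).
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ConfigurationError("threshold_scan requires a non-empty threshold list")
    dataset = list(dataset)
    if not dataset:
        raise ConfigurationError("threshold_scan requires a non-empty dataset")
    diffs = []
    for pair in dataset:
        i1 = model.denoise(pair.ldct)
        diffs.append(difference_image(pair.ndct, i1))
    rows = []
    for t in thresholds:
        fracs = [make_mask(d, t).retained_fraction for d in diffs]
        rows.append(
            {
                "threshold": t,
                "retained_fraction": float(np.mean(fracs)),
                "image_fraction_mean": float(np.mean(fracs)),
                "image_fraction_std": float(np.std(fracs)),
            }
        )
        if dump_dir is not None:
            _dump_panels(Path(dump_dir), dataset[0], diffs[0], t)
    return pd.DataFrame(rows)


def _dump_panels(dump_dir: Path, pair, diff: np.ndarray, threshold: float) -> None:
    from .data_io import write_image

    dump_dir.mkdir(parents=True, exist_ok=True)
    mask = make_mask(diff, threshold)
    tag = f"t{threshold:g}".replace(".", "p")
    write_image(dump_dir / f"difference_{tag}.png", np.clip(np.abs(diff), 0, 1))
    write_image(dump_dir / f"mask_{tag}.png", mask.mask)
    write_image(dump_dir / f"filtered_ldct_{tag}.png", apply_mask(pair.ldct, mask))
    write_image(dump_dir / f"filtered_ndct_{tag}.png", apply_mask(pair.ndct, mask))


def suggest_threshold(scan: pd.DataFrame, band=(0.05, 0.20)) -> float:
    """Smallest scanned threshold whose retained fraction falls in ``band``.

    The band is a quantitative proxy for "filter most flat areas but keep
    the subtle structures": retaining 5-20% of pixels keeps the correction
    pass focused without blanking the image. Falls back to the smallest
    threshold at or below the band's upper edge, then to the largest
    threshold scanned. The user makes the final call.
    """
    lo, hi = band
    table = scan.sort_values("threshold")
    in_band = table[(table.retained_fraction >= lo) & (table.retained_fraction <= hi)]
    if len(in_band):
        return float(in_band.threshold.iloc[0])
    below = table[table.retained_fraction <= hi]
    if len(below):
        return float(below.threshold.iloc[0])
    return float(table.threshold.iloc[-1])
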