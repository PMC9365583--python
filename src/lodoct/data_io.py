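"""Reading, writing, normalizing and batching slice pairs; run configuration.

Array container
    ``.npz`` files written here are ordinary zip archives holding a single
    ``image.npy`` payload, assembled with fixed zip metadata so identical
    arrays produce byte-identical files (reproducible fixtures).

Raster fallback
    16-bit grayscale PNG/TIFF: intensities in [0, 1] are scaled to the full
    uint16 range on write and back on read.

DICOM
    Read-only; the rescale slope/intercept are applied to obtain HU before
    any windowing, per standard DICOM semantics.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict, fields as dc_fields, is_dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .data_sim import ImagePair
from .errors import ConfigurationError, PairingError
from .losses import LossWeights, MsSsimParams
from .network import NetworkConfig

__all__ = [
    "NormalizationSpec",
    "TrainConfig",
    "DataConfig",
    "RunConfig",
    "write_image",
    "read_image",
    "read_pair",
    "pair_dicom_series",
    "load_config",
    "save_config",
    "batch_pairs",
]

_RASTER_SUFFIXES = {".png", ".tif", ".tiff"}


@dataclass
class NormalizationSpec:
    """How source intensities are mapped to the common [0, 1] scale.

    ``global_minmax`` uses the joint min/max of the two images of a pair
    (one shared affine map); ``fixed_window`` maps the window
    [window_low, window_high] (source units, HU for DICOM) to [0, 1] and
    clips outside it.
    """

    mode: str = "global_minmax"
    window_low: float = 0.0
    window_high: float = 1.0

    def validate(self) -> "NormalizationSpec":
        if self.mode not in ("global_minmax", "fixed_window"):
            raise ConfigurationError(f"unknown normalization mode {self.mode!r}")
        if self.mode == "fixed_window" and not self.window_low < self.window_high:
            raise ConfigurationError("window_low must be < window_high")
        return self


@dataclass
class TrainConfig:
    """Optimization schedule: Adam(0.9, 0.999), batch 8, learning rate 1e-4
    dropping to 5e-5 at epoch 130 of the mechanism phase."""

    batch_size: int = 8
    learning_rate: float = 1e-4
    lr_after_drop: float = 5e-5
    lr_drop_epoch: int = 130
    beta1: float = 0.9
    beta2: float = 0.999

    def validate(self) -> "TrainConfig":
        if self.batch_size < 1:
            raise ConfigurationError(f"batch_size must be >= 1, got {self.batch_size}")
        for name in ("learning_rate", "lr_after_drop"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("beta1", "beta2"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1)")
        if self.lr_drop_epoch < 1:
            raise ConfigurationError("lr_drop_epoch must be >= 1")
        return self


@dataclass
class DataConfig:
    train_dir: str = ""
    val_dir: str = ""
    normalization: NormalizationSpec = field(default_factory=NormalizationSpec)

    def validate(self) -> "DataConfig":
        self.normalization.validate()
        return self


def _default_mechanism():
    from .local_filter import MechanismConfig

    return MechanismConfig()


@dataclass
class RunConfig:
    """Everything one training run needs; round-trips through YAML/JSON."""

    network: NetworkConfig = field(default_factory=NetworkConfig)
    loss_weights: LossWeights = field(default_factory=LossWeights)
    ms_ssim: MsSsimParams = field(default_factory=MsSsimParams)
    mechanism: object = field(default_factory=_default_mechanism)
    trainer: TrainConfig = field(default_factory=TrainConfig)
    data: DataConfig = field(default_factory=DataConfig)
    seed: int = 0

    def validate(self) -> "RunConfig":
        for sub in (self.network, self.loss_weights, self.ms_ssim, self.mechanism,
                    self.trainer, self.data):
            sub.validate()
        return self


# -- images -----------------------------------------------------------------


def write_image(path, image: np.ndarray) -> None:
    """Write a 2-D image; format chosen by suffix (.npz or 16-bit raster)."""
    path = Path(path)
    image = np.asarray(image)
    try:
        if path.suffix == ".npz":
            buf = io.BytesIO()
            np.save(buf, image.astype(np.float64))
            with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
                zf.writestr(zipfile.ZipInfo("image.npy"), buf.getvalue())
        elif path.suffix.lower() in _RASTER_SUFFIXES:
            scaled = np.clip(np.round(image * 65535.0), 0, 65535).astype(np.uint16)
            iio.imwrite(path, scaled)
        else:
            raise ConfigurationError(f"unsupported image format {path.suffix!r}")
    except OSError as exc:
        raise OSError(f"cannot write image to {path}: {exc}") from exc


def read_image(path) -> np.ndarray:
    """Read a 2-D image in source units (raster images return [0, 1])."""
    path = Path(path)
    try:
        if path.suffix == ".npz":
            with zipfile.ZipFile(path) as zf:
                return np.load(io.BytesIO(zf.read("image.npy")))
        if path.suffix.lower() in _RASTER_SUFFIXES:
            return np.asarray(iio.imread(path), dtype=np.float64) / 65535.0
        if path.suffix.lower() in (".dcm", ".ima", ""):
            return _read_dicom(path)
        raise ConfigurationError(f"unsupported image format {path.suffix!r}")
    except OSError as exc:
        raise OSError(f"cannot read image from {path}: {exc}") from exc


def _read_dicom(path) -> np.ndarray:
    import pydicom

    ds = pydicom.dcmread(path)
    img = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    return img * slope + intercept


def normalize_pair(
    ldct: np.ndarray, ndct: np.ndarray, norm: NormalizationSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one shared affine map to both images and clip to [0, 1]."""
    norm.validate()
    if norm.mode == "global_minmax":
        lo = min(float(ldct.min()), float(ndct.min()))
        hi = max(float(ldct.max()), float(ndct.max()))
        if hi <= lo:
            return np.clip(ldct, 0.0, 1.0), np.clip(ndct, 0.0, 1.0)
    else:
        lo, hi = norm.window_low, norm.window_high
    scale = hi - lo
    return (
        np.clip((ldct - lo) / scale, 0.0, 1.0),
        np.clip((ndct - lo) / scale, 0.0, 1.0),
    )


def read_pair(path_ldct, path_ndct, norm: NormalizationSpec | None = None) -> ImagePair:
    """Read two registered slices and normalize them onto one [0, 1] scale."""
    norm = norm if norm is not None else NormalizationSpec()
    ldct = read_image(path_ldct)
    ndct = read_image(path_ndct)
    if ldct.shape != ndct.shape:
        raise PairingError(
            f"pixel dimensions differ: {path_ldct} is {ldct.shape}, "
            f"{path_ndct} is {ndct.shape}"
        )
    provenance = "dicom" if Path(path_ldct).suffix.lower() in (".dcm", ".ima", "") else "file"
    ldct, ndct = normalize_pair(ldct, ndct, norm)
    return ImagePair(ldct=ldct, ndct=ndct, provenance=provenance).validate()


def pair_dicom_series(ldct_dir, ndct_dir) -> list[tuple[Path, Path]]:
    """Pair two DICOM series by sorted slice position; count mismatch is fatal."""
    import pydicom

    def sorted_slices(d):
        paths = sorted(Path(d).glob("*"))
        keyed = []
        for p in paths:
            if not p.is_file():
                continue
            ds = pydicom.dcmread(p, stop_before_pixels=True)
            pos = getattr(ds, "ImagePositionPatient", None)
            key = float(pos[2]) if pos is not None else float(ds.InstanceNumber)
            keyed.append((key, p))
        return [p for _, p in sorted(keyed)]

    low, normal = sorted_slices(ldct_dir), sorted_slices(ndct_dir)
    if len(low) != len(normal):
        raise PairingError(
            f"series lengths differ: {len(low)} low-dose vs {len(normal)} normal-dose slices"
        )
    return list(zip(low, normal))


# -- configuration ------------------------------------------------------------

_TUPLE_FIELDS = {"intensity_range", "scale_weights"}


def _from_dict(cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise ConfigurationError(f"{context}: expected a mapping, got {type(data).__name__}")
    known = {f.name: f for f in dc_fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            raise ConfigurationError(f"{context}: unknown key {key!r}")
        sub_cls = _nested_class(cls, key)
        if sub_cls is not None and isinstance(value, dict):
            value = _from_dict(sub_cls, value, f"{context}.{key}")
        elif key in _TUPLE_FIELDS and isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def _nested_class(cls, key):
    from .local_filter import MechanismConfig

    nested = {
        "network": NetworkConfig,
        "loss_weights": LossWeights,
        "ms_ssim": MsSsimParams,
        "mechanism": MechanismConfig,
        "trainer": TrainConfig,
        "data": DataConfig,
        "normalization": NormalizationSpec,
    }
    return nested.get(key)


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Unspecified fields take the package defaults; unknown keys and invalid
    values raise :class:`ConfigurationError` naming the offending key.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    cfg = _from_dict(RunConfig, data, "config")
    return cfg.validate()


def _listify(obj):
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    return obj


def save_config(cfg: RunConfig, path) -> None:
    path = Path(path)
    data = _listify(asdict(cfg))
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


# -- batching -----------------------------------------------------------------


def batch_pairs(pairs, batch_size: int, shuffle_seed: int = 0) -> list[list]:
    """Shuffle pairs deterministically and split into batches.

    Every pair appears exactly once; the final batch may be short. An empty
    input yields an empty list.
    """
    if batch_size < 1:
        raise ConfigurationError(f"batch_size must be >= 1, got {batch_size}")
    pairs = list(pairs)
    if not pairs:
        return []
    order = np.random.default_rng(shuffle_seed).permutation(len(pairs))
    shuffled = [pairs[i] for i in order]
    return [shuffled[i : i + batch_size] for i in range(0, len(shuffled), batch_size)]
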