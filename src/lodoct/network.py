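"""The improved DD-Net denoiser.

A four-level (by default) encoder/decoder for single-channel CT slices:

* a 7x7 stem convolution (16 channels);
* per encoder level, 2x2 max pooling followed by an improved residual dense
  block (IRDB): a densely connected chain of 3x3 convolutions without batch
  normalization, a 1x1 local-fusion convolution widening to the bottleneck
  width, an enhanced-residual sub-block (two 3x3 convolutions with a local
  skip), a 1x1 projection back to the block's input width, and an identity
  skip from block input to block output;
* per decoder level, nearest-neighbour 2x upsampling, concatenation with the
  encoder feature of the same spatial size, then two "deconvolution"
  (stride-1 transposed convolution) layers each followed by ReLU and batch
  normalization: a 5x5 layer to the decoder width and a 1x1 layer back to
  the stem width;
* a final 1x1 deconvolution producing the single-channel output, with no
  activation.

With ``use_irdb=False`` the enhanced-residual sub-block and the identity
skip are dropped, leaving the plain dense block of the original DD-Net; this
is the ablation toggle.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .errors import ConfigurationError, ShapeError

__all__ = [
    "NetworkConfig",
    "DenoisingModel",
    "build_model",
    "layer_census",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    Defaults are the full-scale network: 16-channel stem, growth 16, four
    dense layers per block (so the dense chain concatenates to the
    80-channel bottleneck width), four resolution levels, 32-channel decoder,
    and Gaussian weight initialization with standard deviation 0.1
    (variance 0.01).
    """

    stem_channels: int = 16
    growth_channels: int = 16
    dense_layers_per_block: int = 4
    bottleneck_channels: int = 80
    n_levels: int = 4
    decoder_channels: int = 32
    use_irdb: bool = True
    init_std: float = 0.1

    def validate(self) -> "NetworkConfig":
        for name in (
            "stem_channels",
            "growth_channels",
            "dense_layers_per_block",
            "bottleneck_channels",
            "n_levels",
            "decoder_channels",
        ):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {v!r}")
        if self.init_std <= 0:
            raise ConfigurationError(f"init_std must be > 0, got {self.init_std!r}")
        return self


class ImprovedResidualDenseBlock(nn.Module):
    """Dense chain + local fusion + enhanced residual sub-block + identity skip."""

    def __init__(self, channels: int, cfg: NetworkConfig, rng):
        super().__init__()
        self.channels = channels
        self.use_irdb = cfg.use_irdb
        std = cfg.init_std
        self.dense = [
            nn.Conv2d(channels + i * cfg.growth_channels, cfg.growth_channels, 3, rng, std)
            for i in range(cfg.dense_layers_per_block)
        ]
        concat_ch = channels + cfg.dense_layers_per_block * cfg.growth_channels
        self.fuse = nn.Conv2d(concat_ch, cfg.bottleneck_channels, 1, rng, std)
        if cfg.use_irdb:
            self.eres1 = nn.Conv2d(cfg.bottleneck_channels, cfg.bottleneck_channels, 3, rng, std)
            self.eres2 = nn.Conv2d(cfg.bottleneck_channels, cfg.bottleneck_channels, 3, rng, std)
        self.project = nn.Conv2d(cfg.bottleneck_channels, channels, 1, rng, std)

    def __call__(self, x: Tensor) -> Tensor:
        if x.data.shape[1] != self.channels:
            raise ShapeError(
                f"block expects {self.channels} channels, got {x.data.shape[1]}"
            )
        feats = x
        for conv in self.dense:
            out = ad.relu(conv(feats))
            feats = ad.concat_channels(feats, out)
        h = ad.relu(self.fuse(feats))
        if self.use_irdb:
            h = h + self.eres2(ad.relu(self.eres1(h)))  # enhanced residual
        h = self.project(h)
        return x + h if self.use_irdb else h


class DecoderStage(nn.Module):
    """Upsample, concatenate the skip, then the two deconvolution layers."""

    def __init__(self, in_ch: int, skip_ch: int, cfg: NetworkConfig, rng):
        super().__init__()
        std = cfg.init_std
        self.deconv1 = nn.Deconv2d(in_ch + skip_ch, cfg.decoder_channels, 5, rng, std)
        self.bn1 = nn.BatchNorm2d(cfg.decoder_channels)
        self.deconv2 = nn.Deconv2d(cfg.decoder_channels, cfg.stem_channels, 1, rng, std)
        self.bn2 = nn.BatchNorm2d(cfg.stem_channels)

    def __call__(self, x: Tensor, skip: Tensor) -> Tensor:
        x = ad.upsample2x(x)
        x = ad.concat_channels(x, skip)
        x = self.bn1(ad.relu(self.deconv1(x)))
        x = self.bn2(ad.relu(self.deconv2(x)))
        return x


class DenoisingModel(nn.Module):
    """Improved DD-Net; maps (N, 1, H, W) in [0,1] to a same-shaped estimate."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        super().__init__()
        cfg.validate()
        self.config = cfg
        rng = np.random.default_rng(seed)
        c = cfg.stem_channels
        self.stem = nn.Conv2d(1, c, 7, rng, cfg.init_std)
        self.blocks = [ImprovedResidualDenseBlock(c, cfg, rng) for _ in range(cfg.n_levels)]
        self.decoders = [DecoderStage(c, c, cfg, rng) for _ in range(cfg.n_levels)]
        self.head = nn.Deconv2d(c, 1, 1, rng, cfg.init_std)

    def __call__(self, x) -> Tensor:
        x = ad.as_tensor(x)
        if x.data.ndim == 2:
            x = ad.Tensor(x.data[None, None])
        if x.data.ndim != 4 or x.data.shape[1] != 1:
            raise ShapeError("input must be (N, 1, H, W) or a single 2-D image")
        div = 2 ** self.config.n_levels
        n, _, h, w = x.data.shape
        if h % div or w % div:
            raise ShapeError(
                f"input height and width must be divisible by {div}, got {h}x{w}"
            )
        feats = ad.relu(self.stem(x))
        skips = [feats]
        for block in self.blocks:
            feats = block(ad.max_pool2d(feats))
            skips.append(feats)
        out = skips[-1]
        for i, dec in enumerate(self.decoders):
            out = dec(out, skips[-2 - i])
        return self.head(out)

    def denoise(self, image: np.ndarray) -> np.ndarray:
        """Eval-mode forward pass on one 2-D image (no graph kept)."""
        was_training = self.training
        self.eval()
        try:
            out = self(np.asarray(image, dtype=np.float64)[None, None])
        finally:
            self.train(was_training)
        return out.data[0, 0]


def build_model(cfg: NetworkConfig | None = None, seed: int = 0) -> DenoisingModel:
    """Construct a seeded model; identical (cfg, seed) gives identical weights."""
    return DenoisingModel(cfg if cfg is not None else NetworkConfig(), seed)


def layer_census(model: DenoisingModel) -> dict:
    """Count the structural elements for audit against the design census."""
    cfg = model.config
    return {
        "stem_convolutions": 1,
        "max_pools": cfg.n_levels,
        "irdb_blocks": len(model.blocks),
        "upsamplings": len(model.decoders),
        "deconvolutions": 2 * len(model.decoders),
        "head_kernel": model.head.kernel,
        "head_channels": model.head.out_ch,
    }


def count_parameters(model: DenoisingModel) -> int:
    return sum(p.data.size for p in model.parameters())


def save_checkpoint(path, model: DenoisingModel, rng_state: dict | None = None) -> None:
    """Write weights, config and optional RNG state as a deterministic zip."""
    payload = {"config": asdict(model.config)}
    if rng_state is not None:
        payload["rng_state"] = rng_state
    zf = zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED)
    with zf:
        info = zipfile.ZipInfo("meta.json")
        zf.writestr(info, json.dumps(payload, sort_keys=True))
        for name, arr in sorted(model.state_dict().items()):
            buf = io.BytesIO()
            np.save(buf, arr)
            zf.writestr(zipfile.ZipInfo(f"weights/{name}.npy"), buf.getvalue())


def load_checkpoint(path) -> tuple[DenoisingModel, dict | None]:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        state = {}
        for name in zf.namelist():
            if name.startswith("weights/"):
                key = name[len("weights/") : -len(".npy")]
                state[key] = np.load(io.BytesIO(zf.read(name)))
    model = DenoisingModel(NetworkConfig(**meta["config"]))
    model.load_state_dict(state)
    return model, meta.get("rng_state")
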