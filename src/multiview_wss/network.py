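"""The multi-view UNet: nested full-scale skip connections for image-to-image
regression of stress maps from geometry renders.

The architecture is a depth-D encoder–decoder built from double-conv blocks
(3×3 conv → batchnorm → ReLU, twice), extended with three skip systems:

* **inter-skips**: each decoder level d receives a 1×1-conv reduction of the
  concatenated encoder maps from levels 1..d, each max-pooled to level-d
  resolution;
* **encoder intra-skips**: encoder level d concatenates the 2×-pooled
  previous level with sigmoid-gated copies of all shallower encoder maps,
  pooled by 2^(d−i);
* **decoder intra-skips**: decoder level d concatenates the 2×-upsampled
  next-deeper decoder map, the inter-skip aggregate, and sigmoid-gated
  bilinear upsamplings (factor 2^(i−d)) of all deeper decoder maps.

The sigmoid gates squash skip features into (0, 1), acting as fixed-form
feature gates on every auxiliary path. ``mode="vanilla_unet"`` disables the
gated paths and reduces inter-skips to the same-level copy, recovering a
plain UNet baseline of the same base width. Channel width at level d is
``base_filters * 2^(d-1)``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .nn import (
    Tensor,
    Module,
    Conv2d,
    ConvBlock,
    concat,
    max_pool,
    sigmoid,
    upsample_bilinear,
)

__all__ = [
    "NetworkConfig",
    "MultiViewUNet",
    "EncoderStage",
    "InterSkip",
    "DecoderStage",
    "build_model",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``input_size`` must be divisible by ``2^(depth-1)`` so every pooling
    level has an integer resolution. Defaults suit full runs; tests use
    ``base_filters=8`` and smaller inputs.
    """

    depth: int = 5
    base_filters: int = 32
    input_size: int = 256
    in_channels: int = 3
    out_channels: int = 3
    mode: str = "multiview"

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.mode not in ("multiview", "vanilla_unet"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.input_size % (2 ** (self.depth - 1)) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by "
                f"2^(depth-1) = {2 ** (self.depth - 1)}")

    def channels(self, level: int) -> int:
        """Feature width at level d (1-indexed from the top)."""
        return self.base_filters * 2 ** (level - 1)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True)
                              .encode()).hexdigest()[:16]


class EncoderStage(Module):
    """Encoder level d ≥ 2 with optional gated intra-skips from levels < d.

    Pool factors for the gated paths are ``2^(d-i)`` for source level i;
    the main path is the 2×-pooled previous level. Everything is
    concatenated and reduced by a double-conv block.
    """

    def __init__(self, config: NetworkConfig, level: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.level = level
        self.gated = config.mode == "multiview"
        self.pool_factors = ([2 ** (level - i) for i in range(1, level)]
                             if self.gated else [])
        in_ch = config.channels(level - 1)
        if self.gated:
            in_ch += sum(config.channels(i) for i in range(1, level))
        self.block = ConvBlock(in_ch, config.channels(level), rng)

    def __call__(self, encoder_maps: list[Tensor]) -> Tensor:
        """``encoder_maps`` holds levels 1..d-1 in order."""
        parts = [max_pool(encoder_maps[-1], 2)]
        if self.gated:
            for i, factor in enumerate(self.pool_factors):
                parts.append(sigmoid(max_pool(encoder_maps[i], factor)))
        return self.block(concat(parts) if len(parts) > 1 else parts[0])


class InterSkip(Module):
    """Full-scale encoder→decoder aggregation for decoder level d.

    Encoder maps from levels 1..d are scaled to level-d resolution
    (max-pooled by ``2^(d-i)`` when shallower, identity at i = d),
    concatenated, and reduced to the level-d width by a 1×1 convolution.
    """

    def __init__(self, config: NetworkConfig, level: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.level = level
        self.scale_factors = [2 ** (level - i) for i in range(1, level + 1)]
        in_ch = sum(config.channels(i) for i in range(1, level + 1))
        self.reduce = Conv2d(in_ch, config.channels(level), 1, rng)

    def __call__(self, encoder_maps: list[Tensor]) -> Tensor:
        """``encoder_maps`` holds levels 1..d in order."""
        parts = []
        for x, factor in zip(encoder_maps, self.scale_factors):
            parts.append(max_pool(x, factor) if factor > 1 else x)
        return self.reduce(concat(parts) if len(parts) > 1 else parts[0])


class DecoderStage(Module):
    """Decoder level d with gated intra-skips from deeper decoder levels.

    Upsample factors for the gated paths are ``2^(i-d)`` for source level
    i = d+1..D (the literal aggregation bound, so level d+1 contributes both
    the main path and a gated copy). In vanilla mode the inputs are just the
    upsampled deeper map and the same-level encoder copy.
    """

    def __init__(self, config: NetworkConfig, level: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.level = level
        self.gated = config.mode == "multiview"
        D = config.depth
        self.up_factors = ([2 ** (i - level) for i in range(level + 1, D + 1)]
                           if self.gated else [])
        in_ch = config.channels(level + 1) + config.channels(level)
        if self.gated:
            in_ch += sum(config.channels(i) for i in range(level + 1, D + 1))
        self.block = ConvBlock(in_ch, config.channels(level), rng)

    def __call__(self, deeper_maps: list[Tensor], lateral: Tensor) -> Tensor:
        """``deeper_maps`` holds decoder levels d+1..D; ``lateral`` is the
        inter-skip aggregate (multiview) or the level-d encoder map (vanilla)."""
        parts = [upsample_bilinear(deeper_maps[0], 2), lateral]
        if self.gated:
            for x, factor in zip(deeper_maps, self.up_factors):
                parts.append(sigmoid(upsample_bilinear(x, factor)))
        return self.block(concat(parts))


class MultiViewUNet(Module):
    """Callable model mapping (B, H, W, 3) images in [0,1] to the same shape.

    The final activation is a sigmoid so outputs are valid color images.
    """

    def __init__(self, config: NetworkConfig, seed: int = 0) -> None:
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        D = config.depth
        self.stem = ConvBlock(config.in_channels, config.channels(1), rng)
        self.encoder_stages = [EncoderStage(config, d, rng) for d in range(2, D + 1)]
        if config.mode == "multiview":
            self.inter_skips = [InterSkip(config, d, rng) for d in range(1, D)]
        else:
            self.inter_skips = []
        self.decoder_stages = [DecoderStage(config, d, rng)
                               for d in range(D - 1, 0, -1)]
        self.head = Conv2d(config.channels(1), config.out_channels, 1, rng)

    def __call__(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x))
        if x.data.ndim != 4 or x.shape[-1] != self.config.in_channels:
            raise ValueError("input must be (B, H, W, C)")
        D = self.config.depth
        enc = [self.stem(x)]
        for stage in self.encoder_stages:
            enc.append(stage(enc))
        dec: dict[int, Tensor] = {D: enc[-1]}
        for stage in self.decoder_stages:
            d = stage.level
            deeper = [dec[i] for i in range(d + 1, D + 1)]
            if self.config.mode == "multiview":
                lateral = self.inter_skips[d - 1](enc[:d])
            else:
                lateral = enc[d - 1]
            dec[d] = stage(deeper, lateral)
        return sigmoid(self.head(dec[1]))

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Inference on (B, H, W, 3) or (H, W, 3) float images in [0,1]."""
        single = images.ndim == 3
        batch = images[None] if single else images
        x = np.ascontiguousarray(batch, dtype=np.float32)
        was_training = self.training
        self.eval()
        out = self(Tensor(x)).data.astype(float)
        self.train(was_training)
        return out[0] if single else out


def build_model(config: NetworkConfig, seed: int = 0) -> MultiViewUNet:
    """Instantiate a model with seeded He-normal initialization."""
    return MultiViewUNet(config, seed=seed)


def save_checkpoint(model: MultiViewUNet, path: str | Path) -> None:
    """Single-file weights (npz) plus a JSON config sidecar with its hash."""
    path = Path(path)
    np.savez(path, **model.state_arrays())
    sidecar = {"config": asdict(model.config),
               "config_hash": model.config.config_hash()}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_checkpoint(path: str | Path) -> MultiViewUNet:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    config = NetworkConfig(**sidecar["config"])
    if config.config_hash() != sidecar["config_hash"]:
        raise ValueError("checkpoint config hash mismatch")
    model = MultiViewUNet(config)
    npz_path = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    with np.load(npz_path if npz_path.exists() else path) as data:
        model.load_state_arrays({k: data[k] for k in data.files})
    return model
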