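"""Encoder-decoder segmentation network with a residual downsampling path.

The encoder applies a processing block (DUCK by default, a plain double
convolution for the ablation) at every resolution, followed by a learned
2x2/stride-2 downscale.  A secondary path of pure strided downscales feeds
the *raw* input into the main path at every resolution by elementwise
addition, so the network always retains the original field of view.  The
coarsest level is processed by residual blocks only (its spatial side is
smaller than the largest block span).  The decoder mirrors the encoder with
nearest-neighbour 2x upsampling, addition skips from the encoder block
outputs, and processing blocks at half the channel width of the level
below.  A 1x1 convolution with a sigmoid produces the probability map.

Channel schedule for base width F and depth D: level i (i 2x downscales
from the input) has F * 2**i channels on the way down; the decoder halves
symmetrically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .blocks import (
    DuckBlock,
    ResidualBlock,
    SimpleConvBlock,
    StridedDownsample,
)
from .nn import Tensor
from .nn.functional import upsample_nearest2x

__all__ = ["ModelConfig", "DuckNet", "build_ducknet", "predict",
           "count_parameters", "save_model", "load_model", "compute_stage_shapes"]

BLOCK_TYPES = ("duck", "simple_conv")


@dataclass(frozen=True)
class ModelConfig:
    filters: int = 17
    input_size: int = 352
    depth: int = 5
    block_type: str = "duck"
    bottleneck_residual_blocks: int = 4
    seed: int = 0
    in_channels: int = 3

    def __post_init__(self):
        if self.filters < 1:
            raise ValueError("filters must be positive")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.input_size % (2 ** self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} is not divisible by 2^depth = {2 ** self.depth}")
        if self.block_type not in BLOCK_TYPES:
            raise ValueError(f"block_type must be one of {BLOCK_TYPES}")
        if self.bottleneck_residual_blocks < 1:
            raise ValueError("bottleneck_residual_blocks must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})


def compute_stage_shapes(config: ModelConfig) -> list[tuple[int, int, int]]:
    """Encoder stage shapes (side, side, channels), level 0 .. depth."""
    shapes = []
    for i in range(config.depth + 1):
        side = config.input_size // (2 ** i)
        channels = config.filters * (2 ** i)
        shapes.append((side, side, channels))
    return shapes


class DuckNet(nn.Module):
    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        F_, D = config.filters, config.depth
        block_cls = DuckBlock if config.block_type == "duck" else SimpleConvBlock

        def ch(i):
            return F_ * (2 ** i)

        # secondary (residual) downsampling path, fed from the raw input
        self.side_down = nn.Sequential()
        side_mods = []
        c = config.in_channels
        for i in range(1, D + 1):
            side_mods.append(StridedDownsample(c, ch(i), rng=rng))
            c = ch(i)
        self.side_down = nn.Sequential(*side_mods)

        # main encoder: block then learned downscale, per level
        enc_blocks, enc_downs = [], []
        for i in range(D):
            cin = config.in_channels if i == 0 else ch(i)
            enc_blocks.append(block_cls(cin, ch(i), rng=rng))
            enc_downs.append(StridedDownsample(ch(i), ch(i + 1), rng=rng))
        self.enc_blocks = nn.Sequential(*enc_blocks)
        self.enc_downs = nn.Sequential(*enc_downs)

        # bottleneck: residual blocks only; first half at the deepest width,
        # second half at half that width to meet the decoder
        n_b = config.bottleneck_residual_blocks
        n_full = n_b // 2  # remaining blocks narrow to ch(D-1) to meet the decoder
        bott = []
        c = ch(D)
        for k in range(n_b):
            width = ch(D) if k < n_full else ch(D - 1)
            bott.append(ResidualBlock(c, width, rng=rng))
            c = width
        self.bottleneck = nn.Sequential(*bott)

        # decoder: upsample, add encoder skip, block at half width
        dec = []
        for i in range(D - 1, -1, -1):
            out_c = ch(i - 1) if i >= 1 else F_
            dec.append(block_cls(ch(i), out_c, rng=rng))
        self.dec_blocks = nn.Sequential(*dec)
        self.head = nn.Conv2d(F_, 1, 1, rng=rng)

        self.stage_shapes = compute_stage_shapes(config)
        self._check_skip_shapes()

    def _check_skip_shapes(self) -> None:
        """Every addition skip must join operands of identical (H, W, C)."""
        D = self.config.depth
        for i in range(1, D + 1):
            side_c = self.side_down.mods[i - 1].conv.weight.shape[0]
            main_c = self.enc_downs.mods[i - 1].conv.weight.shape[0] if i <= D else None
            expected = self.stage_shapes[i][2]
            if side_c != expected or (main_c is not None and main_c != expected):
                raise AssertionError(
                    f"skip at level {i}: side={side_c} main={main_c} expected={expected}")

    def forward(self, x: Tensor) -> Tensor:
        D = self.config.depth

        # secondary path: raw input downscaled to every resolution
        side = []
        s = x
        for mod in self.side_down.mods:
            s = mod(s)
            side.append(s)

        # encoder
        skips = []
        h = x
        for i in range(D):
            t = self.enc_blocks.mods[i](h)
            skips.append(t)
            h = self.enc_downs.mods[i](t) + side[i]

        h = self.bottleneck(h)

        # decoder
        for j, i in enumerate(range(D - 1, -1, -1)):
            h = upsample_nearest2x(h) + skips[i]
            h = self.dec_blocks.mods[j](h)

        return self.head(h).sigmoid()


def build_ducknet(config: ModelConfig) -> DuckNet:
    return DuckNet(config)


def count_parameters(model: DuckNet) -> int:
    return model.num_parameters()


def _as_batch(images: np.ndarray) -> np.ndarray:
    images = np.asarray(images, dtype=np.float32)
    if images.ndim == 3:
        images = images[None]
    if images.ndim != 4 or images.shape[3] not in (1, 3):
        raise ValueError(f"expected (N, H, W, C) images, got shape {images.shape}")
    return images


def predict(model: DuckNet, images: np.ndarray, batch_size: int = 8) -> np.ndarray:
    """Run inference on a batch of HWC images in [0, 1].

    Returns per-pixel foreground probabilities, shape (N, H, W).
    """
    x = _as_batch(images)
    size = model.config.input_size
    if x.shape[1] != size or x.shape[2] != size:
        raise ValueError(
            f"images must be {size}x{size} (resize first), got {x.shape[1]}x{x.shape[2]}")
    if x.min() < 0 or x.max() > 1:
        raise ValueError("image values must lie in [0, 1]")
    model.eval()
    outs = []
    for i in range(0, x.shape[0], batch_size):
        out = model(Tensor(x[i:i + batch_size]))
        outs.append(out.data[..., 0])
    return np.concatenate(outs, axis=0)


def save_model(model: DuckNet, path) -> None:
    """Serialize weights (npz) with the config embedded as JSON metadata."""
    path = Path(path)
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_model(path) -> DuckNet:
    path = Path(path)
    if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
        path = path.with_suffix(path.suffix + ".npz")
    with np.load(path) as data:
        config = ModelConfig.from_dict(
            json.loads(bytes(data["__config__"].tobytes()).decode()))
        model = DuckNet(config)
        state = {k: data[k] for k in data.files if k != "__config__"}
    model.load_state_dict(state)
    return model
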