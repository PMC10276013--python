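"""Multi-scale convolutional blocks and a receptive-field measurement oracle.

Each block maps an (N, C, H, W) feature map to (N, filters, H, W) without
changing the spatial size.  The block family covers three ways of emulating
a large dense kernel with cheaper operations:

==================  =========================================  ==============
block               structure                                  receptive field
==================  =========================================  ==============
residual (x1/2/3)   two 3x3 convs + shortcut, chained          5 / 9 / 13
midscope            3x3 convs at dilations 1, 2                7
widescope           3x3 convs at dilations 1, 2, 4             15
separated           1xN then Nx1 (default N=13)                N
duck                six of the above in parallel, summed       max = 15
simple_conv         plain pair of 3x3 convs (ablation)         5
==================  =========================================  ==============

Dilation schedules are the minimal-depth solutions of 1 + sum(2*d_i) equal
to the target span (7 for midscope, 15 for widescope).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "BlockSpec",
    "BLOCK_KINDS",
    "ResidualBlock",
    "ResidualChain",
    "MidscopeBlock",
    "WidescopeBlock",
    "SeparatedBlock",
    "DuckBlock",
    "SimpleConvBlock",
    "StridedDownsample",
    "make_block",
    "residual_block",
    "residual_chain",
    "midscope_block",
    "widescope_block",
    "separated_block",
    "duck_block",
    "simple_conv_block",
    "strided_downsample",
    "measure_receptive_field",
    "ProbeTooSmallError",
]

BLOCK_KINDS = (
    "residual",
    "midscope",
    "widescope",
    "separated",
    "duck",
    "simple_conv",
    "strided_downsample",
)

MIDSCOPE_DILATIONS = (1, 2)
WIDESCOPE_DILATIONS = (1, 2, 4)
DEFAULT_SEPARATED_LENGTH = 13


@dataclass(frozen=True)
class BlockSpec:
    """Declarative description of a block, the config-file vocabulary."""

    kind: str
    filters: int
    residual_repeats: int = 1
    separated_length: int = DEFAULT_SEPARATED_LENGTH

    def __post_init__(self):
        if self.kind not in BLOCK_KINDS:
            raise ValueError(f"unknown block kind {self.kind!r}")
        if self.filters < 1:
            raise ValueError("filters must be a positive integer")
        if self.residual_repeats not in (1, 2, 3):
            raise ValueError("residual_repeats must be 1, 2 or 3")
        if self.separated_length < 3 or self.separated_length % 2 == 0:
            raise ValueError("separated_length must be odd and >= 3")


def _check_filters(filters: int) -> None:
    if not isinstance(filters, (int, np.integer)) or filters < 1:
        raise ValueError(f"filters must be a positive integer, got {filters!r}")


def _norm(channels: int, enabled: bool) -> nn.Module:
    return nn.BatchNorm2d(channels) if enabled else nn.Identity()


class ResidualBlock(nn.Module):
    """Two 3x3 convolutions plus a shortcut, combined by addition.

    The shortcut is a 1x1 convolution when the channel count changes and
    the identity otherwise; a single block spans a 5x5 input neighbourhood.
    """

    def __init__(self, in_channels: int, filters: int, *, norm: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        _check_filters(filters)
        self.conv1 = nn.Conv2d(in_channels, filters, 3, rng=rng)
        self.conv2 = nn.Conv2d(filters, filters, 3, rng=rng)
        if in_channels != filters:
            self.shortcut = nn.Conv2d(in_channels, filters, 1, rng=rng)
        else:
            self.shortcut = nn.Identity()
        self.bn = _norm(filters, norm)

    def forward(self, x: Tensor) -> Tensor:
        main = self.conv2(self.conv1(x).relu()).relu()
        return self.bn(main + self.shortcut(x))


class ResidualChain(nn.Module):
    """One, two or three residual blocks in sequence (spans 5/9/13)."""

    def __init__(self, in_channels: int, filters: int, repeats: int, *,
                 norm: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        if repeats not in (1, 2, 3):
            raise ValueError(f"repeats must be 1, 2 or 3, got {repeats!r}")
        blocks = []
        c = in_channels
        for _ in range(repeats):
            blocks.append(ResidualBlock(c, filters, norm=norm, rng=rng))
            c = filters
        self.chain = nn.Sequential(*blocks)

    def forward(self, x: Tensor) -> Tensor:
        return self.chain(x)


class MidscopeBlock(nn.Module):
    """3x3 convolutions at dilations 1 and 2: a 7x7 span at 3x3 cost."""

    def __init__(self, in_channels: int, filters: int, *, norm: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        _check_filters(filters)
        self.conv1 = nn.Conv2d(in_channels, filters, 3, dilation=MIDSCOPE_DILATIONS[0], rng=rng)
        self.bn1 = _norm(filters, norm)
        self.conv2 = nn.Conv2d(filters, filters, 3, dilation=MIDSCOPE_DILATIONS[1], rng=rng)
        self.bn2 = _norm(filters, norm)

    def forward(self, x: Tensor) -> Tensor:
        x = self.bn1(self.conv1(x).relu())
        return self.bn2(self.conv2(x).relu())


class WidescopeBlock(nn.Module):
    """3x3 convolutions at dilations 1, 2 and 4: a 15x15 span."""

    def __init__(self, in_channels: int, filters: int, *, norm: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        _check_filters(filters)
        convs = []
        c = in_channels
        for d in WIDESCOPE_DILATIONS:
            convs.append(nn.Conv2d(c, filters, 3, dilation=d, rng=rng))
            convs.append(nn.ReLU())
            convs.append(_norm(filters, norm))
            c = filters
        self.body = nn.Sequential(*convs)

    def forward(self, x: Tensor) -> Tensor:
        return self.body(x)


class SeparatedBlock(nn.Module):
    """Spatially factorized convolution: 1xN followed by Nx1.

    Emulates an NxN kernel with 2N weights per channel pair instead of N^2,
    at the price of a rank-1 kernel restriction (loss of diagonality).
    """

    def __init__(self, in_channels: int, filters: int,
                 n: int = DEFAULT_SEPARATED_LENGTH, *, norm: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        _check_filters(filters)
        if n < 3 or n % 2 == 0:
            raise ValueError(f"separated kernel length must be odd and >= 3, got {n}")
        self.n = n
        self.conv_h = nn.Conv2d(in_channels, filters, (1, n), rng=rng)
        self.bn1 = _norm(filters, norm)
        self.conv_v = nn.Conv2d(filters, filters, (n, 1), rng=rng)
        self.bn2 = _norm(filters, norm)

    def forward(self, x: Tensor) -> Tensor:
        x = self.bn1(self.conv_h(x).relu())
        return self.bn2(self.conv_v(x).relu())


class DuckBlock(nn.Module):
    """Six parallel block variants combined by elementwise addition.

    Branches: widescope, midscope, residual chains of length 1, 2 and 3,
    and a separated block.  The input is normalized before branching and
    the branch sum is normalized again afterwards.
    """

    N_BRANCHES = 6

    def __init__(self, in_channels: int, filters: int, *, norm: bool = True,
                 separated_length: int = DEFAULT_SEPARATED_LENGTH,
                 rng: np.random.Generator | None = None):
        super().__init__()
        _check_filters(filters)
        self.bn_in = _norm(in_channels, norm)
        self.widescope = WidescopeBlock(in_channels, filters, norm=norm, rng=rng)
        self.midscope = MidscopeBlock(in_channels, filters, norm=norm, rng=rng)
        self.res1 = ResidualChain(in_channels, filters, 1, norm=norm, rng=rng)
        self.res2 = ResidualChain(in_channels, filters, 2, norm=norm, rng=rng)
        self.res3 = ResidualChain(in_channels, filters, 3, norm=norm, rng=rng)
        self.separated = SeparatedBlock(in_channels, filters, separated_length,
                                        norm=norm, rng=rng)
        self.bn_out = _norm(filters, norm)

    def branch_outputs(self, x: Tensor) -> list[Tensor]:
        x = self.bn_in(x)
        return [
            self.widescope(x),
            self.midscope(x),
            self.res1(x),
            self.res2(x),
            self.res3(x),
            self.separated(x),
        ]

    def forward(self, x: Tensor) -> Tensor:
        outs = self.branch_outputs(x)
        total = outs[0]
        for o in outs[1:]:
            total = total + o
        return self.bn_out(total)


class SimpleConvBlock(nn.Module):
    """Classic U-Net stage: two 3x3 convolutions (the ablation baseline)."""

    def __init__(self, in_channels: int, filters: int, *, norm: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        _check_filters(filters)
        self.conv1 = nn.Conv2d(in_channels, filters, 3, rng=rng)
        self.bn1 = _norm(filters, norm)
        self.conv2 = nn.Conv2d(filters, filters, 3, rng=rng)
        self.bn2 = _norm(filters, norm)

    def forward(self, x: Tensor) -> Tensor:
        x = self.bn1(self.conv1(x).relu())
        return self.bn2(self.conv2(x).relu())


class StridedDownsample(nn.Module):
    """Learned 2x downscale: a 2x2 convolution with stride 2 (no activation)."""

    def __init__(self, in_channels: int, filters: int, *,
                 rng: np.random.Generator | None = None):
        super().__init__()
        _check_filters(filters)
        self.conv = nn.DownConv2d(in_channels, filters, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(x)


def make_block(spec: BlockSpec, in_channels: int, *, norm: bool = True,
               rng: np.random.Generator | None = None) -> nn.Module:
    """Instantiate the block module described by ``spec``."""
    kind, f = spec.kind, spec.filters
    if kind == "residual":
        return ResidualChain(in_channels, f, spec.residual_repeats, norm=norm, rng=rng)
    if kind == "midscope":
        return MidscopeBlock(in_channels, f, norm=norm, rng=rng)
    if kind == "widescope":
        return WidescopeBlock(in_channels, f, norm=norm, rng=rng)
    if kind == "separated":
        return SeparatedBlock(in_channels, f, spec.separated_length, norm=norm, rng=rng)
    if kind == "duck":
        return DuckBlock(in_channels, f, norm=norm,
                         separated_length=spec.separated_length, rng=rng)
    if kind == "simple_conv":
        return SimpleConvBlock(in_channels, f, norm=norm, rng=rng)
    if kind == "strided_downsample":
        return StridedDownsample(in_channels, f, rng=rng)
    raise ValueError(f"unknown block kind {kind!r}")  # pragma: no cover


# -- functional surface ------------------------------------------------------
#
# Convenience wrappers operating on HWC numpy arrays: build a freshly seeded
# block, run it in inference mode and return the result as HWC.  Mostly
# useful interactively and in tests; training uses the Module classes.


def _apply(module: nn.Module, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float32)
    if x.ndim != 3 or x.shape[2] < 1 or x.shape[0] < 1 or x.shape[1] < 1:
        raise ValueError(f"expected a non-empty HWC array, got shape {x.shape}")
    module.eval()
    out = module(Tensor(x[None]))
    return out.data[0]


def _rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def residual_block(x: np.ndarray, filters: int, *, seed=0) -> np.ndarray:
    return _apply(ResidualBlock(np.asarray(x).shape[2], filters, rng=_rng(seed)), x)


def residual_chain(x: np.ndarray, filters: int, repeats: int, *, seed=0) -> np.ndarray:
    return _apply(ResidualChain(np.asarray(x).shape[2], filters, repeats, rng=_rng(seed)), x)


def midscope_block(x: np.ndarray, filters: int, *, seed=0) -> np.ndarray:
    return _apply(MidscopeBlock(np.asarray(x).shape[2], filters, rng=_rng(seed)), x)


def widescope_block(x: np.ndarray, filters: int, *, seed=0) -> np.ndarray:
    return _apply(WidescopeBlock(np.asarray(x).shape[2], filters, rng=_rng(seed)), x)


def separated_block(x: np.ndarray, filters: int, n: int = DEFAULT_SEPARATED_LENGTH,
                    *, seed=0) -> np.ndarray:
    return _apply(SeparatedBlock(np.asarray(x).shape[2], filters, n, rng=_rng(seed)), x)


def duck_block(x: np.ndarray, filters: int, *, seed=0) -> np.ndarray:
    return _apply(DuckBlock(np.asarray(x).shape[2], filters, rng=_rng(seed)), x)


def simple_conv_block(x: np.ndarray, filters: int, *, seed=0) -> np.ndarray:
    return _apply(SimpleConvBlock(np.asarray(x).shape[2], filters, rng=_rng(seed)), x)


def strided_downsample(x: np.ndarray, filters: int, *, seed=0) -> np.ndarray:
    return _apply(StridedDownsample(np.asarray(x).shape[2], filters, rng=_rng(seed)), x)


# -- receptive-field oracle --------------------------------------------------


class ProbeTooSmallError(ValueError):
    """The gradient footprint touched the probe border; enlarge the probe."""


def _force_positive_weights(module: nn.Module) -> None:
    """Make every conv weight and bias positive so ReLUs stay active and no
    gradient cancellation can shrink the measured footprint."""
    for name, p in module.named_parameters():
        leaf = name.rsplit(".", 1)[-1]
        if leaf == "weight":
            p.data = np.full_like(p.data, 0.05)
        elif leaf == "bias":
            p.data = np.full_like(p.data, 0.1)
        elif leaf == "gamma":
            p.data = np.ones_like(p.data)
        elif leaf == "beta":
            p.data = np.zeros_like(p.data)


def measure_receptive_field(block, probe_size: int = 41,
                            in_channels: int = 1) -> tuple[int, int]:
    """Measure a block's receptive field by its gradient footprint.

    The block (a :class:`BlockSpec` or a ready ``Module``) is run on a
    constant probe image; the gradient of the central output unit with
    respect to the input marks exactly the input positions that influence
    it.  Returns the (height, width) side lengths of the bounding box of
    nonzero gradients.

    Raises :class:`ProbeTooSmallError` when the footprint reaches the probe
    border, i.e. the true field may exceed the probe.
    """
    if probe_size < 3:
        raise ValueError("probe_size must be >= 3")
    if isinstance(block, BlockSpec):
        module = make_block(block, in_channels, rng=np.random.default_rng(0))
    else:
        module = block
    _force_positive_weights(module)
    module.eval()

    x = Tensor(np.ones((1, probe_size, probe_size, in_channels), dtype=np.float32),
               requires_grad=True)
    out = module(x)
    c = probe_size // 2
    grad_seed = np.zeros_like(out.data)
    grad_seed[:, c, c, :] = 1.0
    out.backward(grad_seed)

    footprint = np.abs(x.grad).max(axis=(0, 3)) > 1e-12
    rows = np.flatnonzero(footprint.any(axis=1))
    cols = np.flatnonzero(footprint.any(axis=0))
    if rows.size == 0:
        raise RuntimeError("no gradient reached the input; dead block?")
    if rows[0] == 0 or cols[0] == 0 or rows[-1] == probe_size - 1 or cols[-1] == probe_size - 1:
        raise ProbeTooSmallError(
            f"gradient footprint touches the {probe_size}x{probe_size} probe border; "
            "increase probe_size")
    return int(rows[-1] - rows[0] + 1), int(cols[-1] - cols[0] + 1)
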