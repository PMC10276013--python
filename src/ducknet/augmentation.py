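"""Paired image/mask augmentation: flips, color jitter, affine transforms.

Geometric transforms (flips and a rotation/translation/scale/shear affine)
are applied with identical sampled parameters to the image and its mask;
color jitter touches the image only.  The mask is resampled with nearest
neighbour and stays strictly binary; the image is bilinear with reflective
border fill and is clipped back to [0, 1].

Every transform parameter is drawn once into a :class:`AugmentParams`
record, which can be replayed to reproduce the augmented pair bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color as skcolor

__all__ = ["AugmentConfig", "AugmentParams", "sample_params", "apply_params",
           "augment_pair"]


@dataclass(frozen=True)
class AugmentConfig:
    p_hflip: float = 0.5
    p_vflip: float = 0.5
    brightness_range: tuple[float, float] = (0.6, 1.6)
    contrast: float = 0.2
    saturation: float = 0.1
    hue: float = 0.01
    rotation_range: tuple[float, float] = (-180.0, 180.0)
    translate_range: tuple[float, float] = (-0.125, 0.125)
    scale_range: tuple[float, float] = (0.5, 1.5)
    # symmetric by default; the asymmetric printed variant (-22.5, 22.0)
    # can be configured explicitly
    shear_range: tuple[float, float] = (-22.5, 22.5)
    enable_jitter: bool = True
    enable_affine: bool = True

    def __post_init__(self):
        for p in (self.p_hflip, self.p_vflip):
            if not 0.0 <= p <= 1.0:
                raise ValueError("flip probabilities must lie in [0, 1]")
        for lo, hi in (self.brightness_range, self.rotation_range,
                       self.translate_range, self.scale_range, self.shear_range):
            if hi < lo:
                raise ValueError("interval bounds must satisfy lo <= hi")
        for f in (self.contrast, self.saturation, self.hue):
            if f < 0:
                raise ValueError("jitter factors must be non-negative")


@dataclass(frozen=True)
class AugmentParams:
    """One draw of every transform parameter; sufficient for exact replay."""

    hflip: bool
    vflip: bool
    brightness: float
    contrast: float
    saturation: float
    hue: float
    rotation_deg: float
    translate: tuple[float, float]  # (dy, dx) as fraction of the side
    scale: float
    shear_deg: float
    apply_jitter: bool = True
    apply_affine: bool = True

    @property
    def affine_is_identity(self) -> bool:
        return (not self.apply_affine
                or (self.rotation_deg == 0.0 and self.translate == (0.0, 0.0)
                    and self.scale == 1.0 and self.shear_deg == 0.0))


def _uniform(rng: np.random.Generator, interval) -> float:
    lo, hi = interval
    return float(lo) if lo == hi else float(rng.uniform(lo, hi))


def sample_params(config: AugmentConfig, rng: np.random.Generator) -> AugmentParams:
    """Draw one parameter record, uniform over each configured interval."""
    return AugmentParams(
        hflip=bool(rng.random() < config.p_hflip),
        vflip=bool(rng.random() < config.p_vflip),
        brightness=_uniform(rng, config.brightness_range),
        contrast=_uniform(rng, (1.0 - config.contrast, 1.0 + config.contrast)),
        saturation=_uniform(rng, (1.0 - config.saturation, 1.0 + config.saturation)),
        hue=_uniform(rng, (-config.hue, config.hue)),
        rotation_deg=_uniform(rng, config.rotation_range),
        translate=(_uniform(rng, config.translate_range),
                   _uniform(rng, config.translate_range)),
        scale=_uniform(rng, config.scale_range),
        shear_deg=_uniform(rng, config.shear_range),
        apply_jitter=config.enable_jitter,
        apply_affine=config.enable_affine,
    )


def _color_jitter(image: np.ndarray, p: AugmentParams) -> np.ndarray:
    out = image * p.brightness
    if p.contrast != 1.0:
        gray_mean = out.mean()
        out = gray_mean + p.contrast * (out - gray_mean)
    if p.saturation != 1.0:
        gray = out.mean(axis=2, keepdims=True)
        out = gray + p.saturation * (out - gray)
    out = np.clip(out, 0.0, 1.0)
    if p.hue != 0.0:
        hsv = skcolor.rgb2hsv(out)
        hsv[..., 0] = (hsv[..., 0] + p.hue) % 1.0
        out = skcolor.hsv2rgb(hsv)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def _affine_matrix(p: AugmentParams, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Inverse (output->input) affine about the image center, row/col coords."""
    h, w = shape
    theta = np.deg2rad(p.rotation_deg)
    phi = np.deg2rad(p.shear_deg)
    # forward map: scale, shear (x by y), rotate, then translate
    scale = np.array([[p.scale, 0.0], [0.0, p.scale]])
    shear = np.array([[1.0, 0.0], [np.tan(phi), 1.0]])  # rows=y, cols=x
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    fwd = rot @ shear @ scale
    inv = np.linalg.inv(fwd)
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    shift = np.array([p.translate[0] * h, p.translate[1] * w])
    # output coord o maps to input coord inv @ (o - center - shift) + center
    offset = center - inv @ (center + shift)
    return inv, offset


def _apply_geometric(arr: np.ndarray, p: AugmentParams, *, is_mask: bool) -> np.ndarray:
    out = arr
    if p.hflip:
        out = out[:, ::-1]
    if p.vflip:
        out = out[::-1, :]
    if not p.affine_is_identity:
        inv, offset = _affine_matrix(p, out.shape[:2])
        order = 0 if is_mask else 1
        mode = "constant" if is_mask else "reflect"
        if out.ndim == 3:
            channels = [ndimage.affine_transform(
                out[..., c], inv, offset=offset, order=order, mode=mode, cval=0.0)
                for c in range(out.shape[2])]
            out = np.stack(channels, axis=2)
        else:
            out = ndimage.affine_transform(out, inv, offset=offset, order=order,
                                           mode=mode, cval=0.0)
    return np.ascontiguousarray(out)


def apply_params(image: np.ndarray, mask: np.ndarray,
                 p: AugmentParams) -> tuple[np.ndarray, np.ndarray]:
    """Replay a parameter record on an (image, mask) pair."""
    image = np.asarray(image, dtype=np.float32)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape[:2]:
        raise ValueError(
            f"image/mask size mismatch: {image.shape[:2]} vs {mask.shape[:2]}")
    out_img = _apply_geometric(image, p, is_mask=False)
    out_mask = _apply_geometric(mask.astype(np.float32), p, is_mask=True)
    if p.apply_jitter:
        out_img = _color_jitter(out_img, p)
    out_img = np.clip(out_img, 0.0, 1.0).astype(np.float32)
    out_mask = (out_mask > 0.5).astype(mask.dtype if mask.dtype.kind in "ui" else np.uint8)
    return out_img, out_mask


def augment_pair(image: np.ndarray, mask: np.ndarray, config: AugmentConfig,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Sample one augmentation and apply it consistently to the pair."""
    return apply_params(image, mask, sample_params(config, rng))
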