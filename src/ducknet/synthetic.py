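"""Synthetic segmentation pairs: textured frames with irregular bright blobs.

Each frame is a smoothly textured background with a radial illumination
vignette, containing 1-3 radially perturbed ellipse "polyps" that are
brighter than their surroundings by a configurable contrast gap and carry
their own texture.  Masks are the exact blob indicator evaluated at target
resolution, so there is no resampling error.  Everything is a pure
function of the seed.

Blob geometry: a point at polar angle theta (in the ellipse frame with
semi-axes a, b) is inside when r <= rho(theta), where

    rho(theta) = 1 + sum_k amp_k * sin(k * theta + phase_k),  k in 3..7

with the total perturbation amplitude capped so rho stays in [0.5, 1.5].
The enclosed area is a * b * 0.5 * integral(rho^2) which is used by the
tests as an analytic area model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .dataio import SamplePair, save_mask

__all__ = ["SynthConfig", "generate_sample", "generate_dataset",
           "difficulty_sweep", "write_dataset", "blob_area_bounds"]

MIN_HARMONIC, MAX_HARMONIC = 3, 7
MAX_PERTURBATION = 0.35  # cap on sum of harmonic amplitudes


@dataclass(frozen=True)
class SynthConfig:
    n_samples: int = 200
    size: int = 64
    blobs_min: int = 1
    blobs_max: int = 3
    blob_radius_fraction: tuple[float, float] = (0.08, 0.35)
    texture_noise_sd: float = 0.05
    contrast_gap: float = 0.35
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if self.size % 32 != 0:
            raise ValueError(f"size must be divisible by 32, got {self.size}")
        if not 1 <= self.blobs_min <= self.blobs_max:
            raise ValueError("need 1 <= blobs_min <= blobs_max")
        lo, hi = self.blob_radius_fraction
        if not (0.0 < lo <= hi < 0.5):
            raise ValueError("blob_radius_fraction must lie within (0, 0.5)")
        if self.contrast_gap < 0:
            raise ValueError("contrast_gap must be non-negative")
        if self.texture_noise_sd < 0:
            raise ValueError("texture_noise_sd must be non-negative")
        # a blob must fit inside the frame together with a 1-pixel border margin
        if hi * (1 + MAX_PERTURBATION) + 1.0 / self.size >= 0.5:
            raise ValueError("blob radius range too large: blobs cannot fit the frame")


def _smooth_noise(rng: np.random.Generator, size: int, sigma: float,
                  sd: float) -> np.ndarray:
    noise = rng.normal(0.0, 1.0, (size, size))
    smooth = ndimage.gaussian_filter(noise, sigma, mode="reflect")
    s = smooth.std()
    if s > 0:
        smooth *= sd / s
    return smooth


def _blob_mask(size: int, center, axes, angle: float, amps, phases) -> np.ndarray:
    """Exact indicator of one radially perturbed ellipse."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dy, dx = yy - center[0], xx - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = (ca * dx + sa * dy) / axes[1]   # ellipse-frame x, normalized
    v = (-sa * dx + ca * dy) / axes[0]  # ellipse-frame y, normalized
    r = np.hypot(u, v)
    theta = np.arctan2(v, u)
    rho = np.ones_like(r)
    for k, amp, phase in zip(range(MIN_HARMONIC, MIN_HARMONIC + len(amps)), amps, phases):
        rho += amp * np.sin(k * theta + phase)
    return (r <= rho).astype(np.uint8)


def _sample_blob(rng: np.random.Generator, config: SynthConfig):
    size = config.size
    lo, hi = config.blob_radius_fraction
    a = rng.uniform(lo, hi) * size
    b = a * rng.uniform(0.6, 1.0)  # mild eccentricity
    n_harm = int(rng.integers(1, MAX_HARMONIC - MIN_HARMONIC + 2))
    amps = rng.uniform(0.0, MAX_PERTURBATION / n_harm, n_harm)
    phases = rng.uniform(0.0, 2 * np.pi, n_harm)
    angle = rng.uniform(0.0, np.pi)
    margin = max(a, b) * (1 + MAX_PERTURBATION) + 1
    center = (rng.uniform(margin, size - margin), rng.uniform(margin, size - margin))
    return center, (a, b), angle, amps, phases


def generate_sample(config: SynthConfig, rng: np.random.Generator,
                    sample_id: str) -> SamplePair:
    size = config.size

    # background: base tone + low-frequency texture + radial vignette
    base = rng.uniform(0.25, 0.4)
    background = base + _smooth_noise(rng, size, sigma=size / 12,
                                      sd=config.texture_noise_sd)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    c = (size - 1) / 2.0
    r2 = ((yy - c) ** 2 + (xx - c) ** 2) / (2 * c * c)
    background = background * (1.0 - 0.35 * r2)  # endoscope-like vignette

    n_blobs = int(rng.integers(config.blobs_min, config.blobs_max + 1))
    mask = np.zeros((size, size), dtype=np.uint8)
    fg_texture = _smooth_noise(rng, size, sigma=size / 24,
                               sd=config.texture_noise_sd)
    for _ in range(n_blobs):
        mask |= _blob_mask(size, *_sample_blob(rng, config))

    lum = np.where(mask, background + config.contrast_gap + fg_texture, background)

    # color: reddish endoscopic tint with per-channel gains
    gains = np.array([1.0, 0.65, 0.55]) + rng.normal(0, 0.03, 3)
    image = np.clip(lum[..., None] * gains[None, None, :], 0.0, 1.0)
    image += rng.normal(0.0, 0.01, image.shape)  # sensor noise
    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    return SamplePair(image=image, mask=mask, id=sample_id)


def generate_dataset(config: SynthConfig) -> list[SamplePair]:
    """Generate ``config.n_samples`` pairs, fully determined by the seed."""
    rng = np.random.default_rng(config.seed)
    width = max(4, len(str(config.n_samples)))
    return [generate_sample(config, rng, f"synth_{i:0{width}d}")
            for i in range(config.n_samples)]


def difficulty_sweep(base: SynthConfig, gaps) -> list[list[SamplePair]]:
    """Datasets identical except for the foreground/background contrast gap.

    ``gaps`` must be sorted in descending order (easy to hard).
    """
    gaps = list(gaps)
    if gaps != sorted(gaps, reverse=True):
        raise ValueError("gaps must be sorted descending (easiest first)")
    return [generate_dataset(replace(base, contrast_gap=g)) for g in gaps]


def blob_area_bounds(config: SynthConfig) -> tuple[float, float]:
    """Analytic bounds on the foreground fraction of one frame.

    Lower bound: a single blob at the smallest radius with the most
    eccentric axis ratio and maximal inward perturbation.  Upper bound:
    ``blobs_max`` non-overlapping blobs at the largest radius with maximal
    outward perturbation.
    """
    lo, hi = config.blob_radius_fraction
    min_area = np.pi * (lo ** 2) * 0.6 * (1 - MAX_PERTURBATION) ** 2
    max_area = config.blobs_max * np.pi * (hi ** 2) * (1 + MAX_PERTURBATION) ** 2
    return float(min_area), float(min(1.0, max_area))


def write_dataset(samples, out_dir) -> None:
    """Write pairs in the images/ + masks/ directory layout (PNG files)."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    from PIL import Image as PILImage

    for s in samples:
        img8 = np.round(s.image * 255).astype(np.uint8)
        PILImage.fromarray(img8).save(out_dir / "images" / f"{s.id}.png")
        save_mask(s.mask.astype(np.float64), out_dir / "masks" / f"{s.id}.png",
                  threshold=0.5)
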