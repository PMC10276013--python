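"""Loading image/mask pairs, Lanczos rescaling, mask I/O and dataset splits.

Datasets are directory pairs ``<root>/images`` and ``<root>/masks`` whose
files are matched by identical stem.  Images are rescaled with a Lanczos
filter (anti-aliased) and masks with nearest neighbour so they remain
binary; 8-bit masks binarize at > 127.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image as PILImage

__all__ = ["SamplePair", "SplitSpec", "load_pair", "load_image", "load_mask",
           "save_mask", "split_dataset", "list_pairs", "load_dataset",
           "write_manifest", "read_manifest"]

IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp")
MASK_BINARIZE_THRESHOLD = 127  # 8-bit midpoint; datasets are nominally {0, 255}


@dataclass
class SamplePair:
    image: np.ndarray  # (H, W, 3) float32 in [0, 1]
    mask: np.ndarray   # (H, W) uint8 in {0, 1}
    id: str

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape[:2]:
            raise ValueError("image and mask spatial sizes differ")


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    val_fraction: float = 0.1
    test_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        total = self.train_fraction + self.val_fraction + self.test_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {total}")
        if min(self.train_fraction, self.val_fraction, self.test_fraction) < 0:
            raise ValueError("split fractions must be non-negative")


def _open(path) -> PILImage.Image:
    path = Path(path)
    try:
        return PILImage.open(path)
    except Exception as exc:  # noqa: BLE001 - surface the offending path
        raise IOError(f"cannot read image file {path}: {exc}") from exc


def load_image(path, target_size: int | None = None) -> np.ndarray:
    """Load an RGB image as float32 in [0, 1], optionally Lanczos-resized."""
    with _open(path) as img:
        img = img.convert("RGB")
        if target_size is not None:
            img = img.resize((target_size, target_size), PILImage.LANCZOS)
        return np.asarray(img, dtype=np.float32) / 255.0


def load_mask(path, target_size: int | None = None) -> np.ndarray:
    """Load a mask as uint8 {0, 1}; nearest-neighbour resize keeps it binary."""
    with _open(path) as img:
        img = img.convert("L")
        if target_size is not None:
            img = img.resize((target_size, target_size), PILImage.NEAREST)
        arr = np.asarray(img)
    return (arr > MASK_BINARIZE_THRESHOLD).astype(np.uint8)


def load_pair(image_path, mask_path, target_size: int | None = None) -> SamplePair:
    """Load a matched image/mask pair, rescaled to ``target_size`` square."""
    image_path, mask_path = Path(image_path), Path(mask_path)
    with _open(image_path) as img, _open(mask_path) as msk:
        if img.size != msk.size:
            warnings.warn(
                f"image/mask size mismatch for {image_path.stem}: "
                f"{img.size} vs {msk.size}; resizing both", stacklevel=2)
    image = load_image(image_path, target_size)
    mask = load_mask(mask_path, target_size)
    if target_size is None and image.shape[:2] != mask.shape[:2]:
        # mismatched originals with no target: conform the mask to the image
        side = image.shape[0]
        mask = load_mask(mask_path, None)
        pil = PILImage.fromarray((mask * 255).astype(np.uint8))
        pil = pil.resize((image.shape[1], image.shape[0]), PILImage.NEAREST)
        mask = (np.asarray(pil) > MASK_BINARIZE_THRESHOLD).astype(np.uint8)
        del side
    return SamplePair(image=image, mask=mask, id=image_path.stem)


def save_mask(mask: np.ndarray, path, threshold: float | None = None) -> None:
    """Write a mask or probability map as a single-channel 8-bit image.

    With a threshold the map is binarized to {0, 255}; without one, values
    in [0, 1] are scaled to 0..255.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"expected a 2-D mask, got shape {mask.shape}")
    if mask.min() < 0 or mask.max() > 1:
        raise ValueError("mask values must lie in [0, 1]")
    if threshold is not None:
        out = ((mask > threshold) * 255).astype(np.uint8)
    else:
        out = np.round(mask.astype(np.float64) * 255).astype(np.uint8)
    path = Path(path)
    try:
        PILImage.fromarray(out, mode="L").save(path)
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"cannot write mask to {path}: {exc}") from exc


def split_dataset(ids, spec: SplitSpec) -> tuple[list[str], list[str], list[str]]:
    """Seeded, disjoint, exhaustive train/val/test partition.

    Sizes are floor(train_fraction*n), floor(val_fraction*n) and the
    remainder, over a seed-determined permutation of the sorted ids.
    """
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("ids must be unique")
    n = len(ids)
    if n < 3:
        raise ValueError(f"need at least 3 samples to split, got {n}")
    order = np.random.default_rng(spec.seed).permutation(sorted(ids))
    n_train = int(np.floor(spec.train_fraction * n))
    n_val = int(np.floor(spec.val_fraction * n))
    train = [str(s) for s in order[:n_train]]
    val = [str(s) for s in order[n_train:n_train + n_val]]
    test = [str(s) for s in order[n_train + n_val:]]
    return train, val, test


def list_pairs(root) -> list[tuple[str, Path, Path]]:
    """Enumerate (id, image_path, mask_path) under root/images + root/masks."""
    root = Path(root)
    img_dir, mask_dir = root / "images", root / "masks"
    if not img_dir.is_dir() or not mask_dir.is_dir():
        raise IOError(f"expected {img_dir} and {mask_dir} directories")
    masks = {p.stem: p for p in mask_dir.iterdir()
             if p.suffix.lower() in IMAGE_EXTENSIONS}
    pairs = []
    for p in sorted(img_dir.iterdir()):
        if p.suffix.lower() not in IMAGE_EXTENSIONS:
            continue
        if p.stem not in masks:
            raise IOError(f"no mask found for image {p.name}")
        pairs.append((p.stem, p, masks[p.stem]))
    if not pairs:
        raise IOError(f"no image/mask pairs found under {root}")
    return pairs


def load_dataset(root, target_size: int, ids=None) -> list[SamplePair]:
    """Load (a subset of) a dataset directory, resized to ``target_size``."""
    pairs = list_pairs(root)
    if ids is not None:
        wanted = set(ids)
        pairs = [p for p in pairs if p[0] in wanted]
        missing = wanted - {p[0] for p in pairs}
        if missing:
            raise IOError(f"manifest ids not found on disk: {sorted(missing)[:10]}")
    return [load_pair(img, msk, target_size) for _, img, msk in pairs]


def write_manifest(ids, path) -> None:
    Path(path).write_text("\n".join(ids) + "\n")


def read_manifest(path) -> list[str]:
    return [line for line in Path(path).read_text().splitlines() if line.strip()]
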