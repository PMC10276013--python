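"""Overlap metrics for binary segmentation and the soft Dice loss.

All metrics are defined through pixel confusion counts with foreground as
the positive class:

    Dice      = 2TP / (2TP + FP + FN)
    Jaccard   = TP / (TP + FP + FN)
    Precision = TP / (TP + FP)
    Recall    = TP / (TP + FN)
    Accuracy  = (TP + TN) / (TP + TN + FP + FN)

Zero-denominator convention: an empty prediction against an empty truth is
a perfect match (metric = 1); when exactly one side is empty the affected
metric is 0.  Accuracy never degenerates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "dice",
    "jaccard",
    "precision",
    "recall",
    "accuracy",
    "dice_loss",
    "evaluate_set",
    "METRIC_NAMES",
]

METRIC_NAMES = ("dice", "jaccard", "precision", "recall", "accuracy")

SMOOTH_EPS = 1e-6


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _as_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1), found values {vals[:5]}")
    return arr.astype(bool)


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts between two binary masks."""
    pred = _as_binary(pred, "pred")
    truth = _as_binary(truth, "truth")
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: int, den: int) -> float:
    if den == 0:
        return 1.0  # both sides empty
    return num / den


def dice(c: ConfusionCounts) -> float:
    return _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)


def jaccard(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fp + c.fn)


def precision(c: ConfusionCounts) -> float:
    if c.tp + c.fp == 0:
        return 1.0 if c.fn == 0 else 0.0
    return c.tp / (c.tp + c.fp)


def recall(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        return 1.0 if c.fp == 0 else 0.0
    return c.tp / (c.tp + c.fn)


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise ValueError("cannot compute accuracy of zero pixels")
    return (c.tp + c.tn) / c.total


def all_metrics(c: ConfusionCounts) -> dict[str, float]:
    return {
        "dice": dice(c),
        "jaccard": jaccard(c),
        "precision": precision(c),
        "recall": recall(c),
        "accuracy": accuracy(c),
    }


def dice_loss(prob: np.ndarray, truth: np.ndarray, eps: float = SMOOTH_EPS) -> float:
    """1 minus the soft Dice coefficient of a probability map vs a mask.

    Soft Dice replaces hard counts with sums of per-pixel products, making
    the loss differentiable in ``prob``; ``eps`` stabilizes the empty case.
    """
    prob = np.asarray(prob, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if prob.shape != truth.shape:
        raise ValueError(f"shape mismatch: prob {prob.shape} vs truth {truth.shape}")
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    inter = float((prob * truth).sum())
    soft_dice = (2.0 * inter + eps) / (prob.sum() + truth.sum() + eps)
    return 1.0 - soft_dice


@dataclass
class MetricsReport:
    """Per-image overlap metrics and their arithmetic means."""

    image_ids: list[str]
    per_image: list[dict[str, float]]
    means: dict[str, float] = field(init=False)

    def __post_init__(self):
        if not self.per_image:
            raise ValueError("report requires at least one image")
        self.means = {
            m: float(np.mean([row[m] for row in self.per_image])) for m in METRIC_NAMES
        }

    @property
    def n_images(self) -> int:
        return len(self.per_image)

    def to_csv(self, path) -> None:
        path = Path(path)
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(("image_id",) + METRIC_NAMES)
            for image_id, row in zip(self.image_ids, self.per_image):
                writer.writerow([image_id] + [f"{row[m]:.6f}" for m in METRIC_NAMES])
            writer.writerow(["mean"] + [f"{self.means[m]:.6f}" for m in METRIC_NAMES])


def evaluate_set(preds, truths, threshold: float = 0.5, image_ids=None,
                 pooled: bool = False) -> MetricsReport:
    """Binarize predictions and score them against ground-truth masks.

    By default metrics are computed per image and averaged ("mean Dice");
    with ``pooled=True`` confusion counts are pooled over all pixels of the
    set and each reported "mean" is the single pooled value.
    """
    preds = list(preds)
    truths = list(truths)
    if not preds:
        raise ValueError("empty evaluation set")
    if len(preds) != len(truths):
        raise ValueError("preds and truths must have equal length")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie strictly inside (0, 1)")
    if image_ids is None:
        image_ids = [str(i) for i in range(len(preds))]

    counts = []
    for p, t in zip(preds, truths):
        p = np.asarray(p)
        hard = (p > threshold).astype(np.uint8) if p.dtype.kind == "f" else p
        counts.append(confusion(hard, t))

    if pooled:
        total = ConfusionCounts(
            sum(c.tp for c in counts), sum(c.fp for c in counts),
            sum(c.fn for c in counts), sum(c.tn for c in counts))
        pooled_row = all_metrics(total)
        return MetricsReport(list(image_ids), [pooled_row for _ in counts])

    rows = [all_metrics(c) for c in counts]
    return MetricsReport(list(image_ids), rows)
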