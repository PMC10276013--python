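"""Training and evaluation loops: soft-Dice objective, RMSprop, seeded runs.

Defaults follow the reference protocol: RMSprop at learning rate 1e-4,
batch size 4, 600 epochs, Dice loss, with the training split re-augmented
every epoch and the best-validation-Dice checkpoint retained.  Smoke-scale
runs override epochs/batch/learning rate explicitly.
"""

from __future__ import annotations

import copy
import csv
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from . import metrics as M
from .augmentation import AugmentConfig, augment_pair
from .dataio import SamplePair, SplitSpec, load_dataset, read_manifest, split_dataset
from .model import DuckNet, ModelConfig, build_ducknet, predict, save_model
from .nn import RMSprop, Tensor

__all__ = ["TrainConfig", "TrainHistory", "train", "evaluate", "cross_evaluate",
           "soft_dice_loss_tensor"]


@dataclass(frozen=True)
class TrainConfig:
    model: ModelConfig = dc_field(default_factory=ModelConfig)
    augment: AugmentConfig | None = dc_field(default_factory=AugmentConfig)
    split: SplitSpec = dc_field(default_factory=SplitSpec)
    learning_rate: float = 1e-4
    batch_size: int = 4
    epochs: int = 600
    threshold: float = 0.5
    checkpoint_policy: str = "best_val_dice"  # or "final"
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.checkpoint_policy not in ("best_val_dice", "final"):
            raise ValueError("checkpoint_policy must be 'best_val_dice' or 'final'")


@dataclass
class TrainHistory:
    train_loss: list[float] = dc_field(default_factory=list)
    val_loss: list[float] = dc_field(default_factory=list)
    val_dice: list[float] = dc_field(default_factory=list)
    best_epoch: int = -1

    @property
    def best_val_dice(self) -> float:
        return self.val_dice[self.best_epoch] if self.best_epoch >= 0 else float("nan")

    def to_csv(self, path) -> None:
        with Path(path).open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "train_loss", "val_loss", "val_dice"])
            for i, (tl, vl, vd) in enumerate(
                    zip(self.train_loss, self.val_loss, self.val_dice)):
                writer.writerow([i, f"{tl:.6f}", f"{vl:.6f}", f"{vd:.6f}"])


EPS = 1e-6


def soft_dice_loss_tensor(prob: Tensor, truth: np.ndarray) -> Tensor:
    """Differentiable per-sample soft Dice loss, averaged over the batch."""
    t = np.asarray(truth, dtype=np.float32)
    inter = (prob * t).sum(axis=(1, 2, 3))
    denom = prob.sum(axis=(1, 2, 3)) + Tensor(t.sum(axis=(1, 2, 3)))
    dice = (2.0 * inter + EPS) / (denom + EPS)
    return (1.0 - dice).mean()


def _stack(samples: list[SamplePair]) -> tuple[np.ndarray, np.ndarray]:
    images = np.stack([s.image for s in samples]).astype(np.float32)
    masks = np.stack([s.mask for s in samples]).astype(np.float32)
    return images, masks


def _forward_loss(model: DuckNet, images: np.ndarray, masks: np.ndarray) -> Tensor:
    prob = model(Tensor(images))
    return soft_dice_loss_tensor(prob, masks[..., None])


def _validate(model: DuckNet, images: np.ndarray, masks: np.ndarray,
              threshold: float, batch_size: int) -> tuple[float, float]:
    model.eval()
    losses, dices = [], []
    for i in range(0, len(images), batch_size):
        probs = predict(model, images[i:i + batch_size], batch_size=batch_size)
        for p, t in zip(probs, masks[i:i + batch_size]):
            losses.append(M.dice_loss(p, t))
            dices.append(M.dice(M.confusion((p > threshold).astype(np.uint8),
                                            t.astype(np.uint8))))
    return float(np.mean(losses)), float(np.mean(dices))


def train(config: TrainConfig, samples: list[SamplePair],
          run_dir=None, verbose: bool = False) -> tuple[DuckNet, TrainHistory]:
    """Train a model on ``samples`` with a seeded 80:10:10 split.

    Returns the checkpoint selected by ``checkpoint_policy`` together with
    the per-epoch history.  Everything stochastic (split, weights, batch
    order, augmentation) derives from the configured seeds.
    """
    if len(samples) < 3:
        raise ValueError("training requires at least 3 samples")
    by_id = {s.id: s for s in samples}
    train_ids, val_ids, _ = split_dataset(sorted(by_id), config.split)
    if not train_ids or not val_ids:
        raise ValueError("empty training or validation split")
    train_set = [by_id[i] for i in train_ids]
    val_images, val_masks = _stack([by_id[i] for i in val_ids])

    model = build_ducknet(config.model)
    opt = RMSprop(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history = TrainHistory()
    best_dice, best_state = -1.0, None

    for epoch in range(config.epochs):
        model.train()
        order = rng.permutation(len(train_set))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            batch = [train_set[j] for j in order[start:start + config.batch_size]]
            if config.augment is not None:
                batch = [
                    SamplePair(*augment_pair(s.image, s.mask, config.augment, rng),
                               id=s.id)
                    for s in batch
                ]
            images, masks = _stack(batch)
            loss = _forward_loss(model, images, masks)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; aborting")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))

        val_loss, val_dice = _validate(model, val_images, val_masks,
                                       config.threshold, config.batch_size)
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(val_loss)
        history.val_dice.append(val_dice)
        if val_dice > best_dice:
            best_dice = val_dice
            best_state = copy.deepcopy(model.state_dict())
            history.best_epoch = epoch
        if verbose:
            print(f"epoch {epoch:4d}  train_loss {history.train_loss[-1]:.4f}  "
                  f"val_loss {val_loss:.4f}  val_dice {val_dice:.4f}")

    if config.checkpoint_policy == "best_val_dice" and best_state is not None:
        model.load_state_dict(best_state)
    model.eval()

    if run_dir is not None:
        run_dir = Path(run_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        save_model(model, run_dir / "model.npz")
        history.to_csv(run_dir / "history.csv")
        for name, ids in (("train", train_ids), ("val", val_ids),
                          ("test", split_dataset(sorted(by_id), config.split)[2])):
            (run_dir / f"{name}_ids.txt").write_text("\n".join(ids) + "\n")
    return model, history


def evaluate(model: DuckNet, samples: list[SamplePair],
             threshold: float = 0.5, batch_size: int = 8,
             pooled: bool = False) -> M.MetricsReport:
    """Score a model on a list of pairs via the standard metric set."""
    if not samples:
        raise ValueError("empty evaluation set")
    images, masks = _stack(samples)
    preds = predict(model, images, batch_size=batch_size)
    return M.evaluate_set(list(preds), [m.astype(np.uint8) for m in masks],
                          threshold=threshold,
                          image_ids=[s.id for s in samples], pooled=pooled)


def evaluate_dir(model: DuckNet, data_dir, manifest=None,
                 threshold: float = 0.5) -> M.MetricsReport:
    """Evaluate on a dataset directory, optionally restricted to a manifest."""
    ids = read_manifest(manifest) if manifest is not None else None
    samples = load_dataset(data_dir, model.config.input_size, ids=ids)
    return evaluate(model, samples, threshold=threshold)


def cross_evaluate(model: DuckNet, samples: list[SamplePair],
                   threshold: float = 0.5) -> M.MetricsReport:
    """Evaluate on a *foreign* dataset in full (no split held out)."""
    return evaluate(model, samples, threshold=threshold)
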