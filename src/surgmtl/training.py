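"""Training and evaluation loop for the multi-task network.

The reference protocol is 30 epochs of shuffled mini-batches of 32 with Adam
at learning rate 1e-4, optimizing the summed segmentation + classification
loss; random rotation/flip augmentation is applied to training batches only.
Per-epoch records mirror the three monitored curves: training loss (total and
per task) and validation Dice / event accuracy. By default the final-epoch
model is kept; selection by best validation Dice is available by flag.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .metrics import MetricReport, classification_accuracy, dice_coefficient, multitask_loss
from .model import MultiTaskUNet, save_checkpoint
from .nn import Adam
from .scenes import DatasetSplits, SceneSample, augment

__all__ = ["TrainConfig", "History", "train", "evaluate", "HISTORY_COLUMNS"]

HISTORY_COLUMNS = [
    "epoch",
    "train_total_loss",
    "train_seg_loss",
    "train_cls_loss",
    "val_dice",
    "val_accuracy",
    "val_acc_class0",
    "val_acc_class1",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-4
    seed: int = 0
    augment: bool = True  # train split only
    checkpoint_dir: str | None = None
    select_best: bool = False  # keep best-val-Dice weights instead of final epoch

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class History:
    """Per-epoch training/validation records."""

    rows: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def column(self, name: str) -> list[float]:
        return [r[name] for r in self.rows]

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=HISTORY_COLUMNS)
            writer.writeheader()
            writer.writerows(self.rows)


def _batch_arrays(samples: list[SceneSample]):
    x = np.stack([s.image.transpose(2, 0, 1) for s in samples]).astype(np.float32)
    yseg = np.stack([s.tool_mask[None].astype(np.float32) for s in samples])
    ycls = np.array([s.event_label for s in samples], dtype=np.int64)
    return x, yseg, ycls


def train(
    model: MultiTaskUNet, splits: DatasetSplits, config: TrainConfig
) -> tuple[MultiTaskUNet, History]:
    """Train in place and return (model, history).

    Shuffling, augmentation, and dropout all draw from one generator seeded
    by ``config.seed``, so identical (seed, data) reruns produce identical
    histories. The last incomplete mini-batch is kept, not dropped.
    """
    if not splits.train:
        raise ValueError("training split is empty")
    h, w, _ = splits.train[0].image.shape
    if (h, w) != (model.config.input_height, model.config.input_width):
        raise ValueError(
            f"sample size {h}x{w} incompatible with model input "
            f"{model.config.input_height}x{model.config.input_width}"
        )

    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    history = History()
    n = len(splits.train)
    best_dice = -1.0
    best_state = None

    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        seg_sum = cls_sum = 0.0
        for start in range(0, n, config.batch_size):
            batch = [splits.train[i] for i in order[start : start + config.batch_size]]
            if config.augment:
                batch = [augment(s, rng) for s in batch]
            x, yseg, ycls = _batch_arrays(batch)
            out = model.forward(x, train=True, rng=rng)
            breakdown, dseg, dcls = multitask_loss(
                out.seg_logits, yseg, out.event_logits, ycls, return_grads=True
            )
            model.zero_grad()
            model.backward(dseg, dcls)
            optimizer.step()
            seg_sum += breakdown.seg_loss * len(batch)
            cls_sum += breakdown.cls_loss * len(batch)

        seg_loss = seg_sum / n
        cls_loss = cls_sum / n
        if splits.val:
            report = evaluate(model, splits.val)
            val_dice = report.dice
            val_acc = report.accuracy
            acc0 = report.per_class_accuracy.get(0, float("nan"))
            acc1 = report.per_class_accuracy.get(1, float("nan"))
        else:
            val_dice = val_acc = acc0 = acc1 = float("nan")
        history.rows.append(
            {
                "epoch": epoch,
                "train_total_loss": seg_loss + cls_loss,
                "train_seg_loss": seg_loss,
                "train_cls_loss": cls_loss,
                "val_dice": val_dice,
                "val_accuracy": val_acc,
                "val_acc_class0": acc0,
                "val_acc_class1": acc1,
            }
        )
        if config.select_best and splits.val and val_dice > best_dice:
            best_dice = val_dice
            best_state = [p.value.copy() for p in model.parameters()]

    if config.select_best and best_state is not None:
        for p, v in zip(model.parameters(), best_state):
            p.value[...] = v
    if config.checkpoint_dir is not None:
        ckpt_dir = Path(config.checkpoint_dir)
        ckpt_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(model, ckpt_dir / "checkpoint.npz")
    return model, history


def evaluate(model, samples: list[SceneSample]) -> MetricReport:
    """Mean per-image Dice (binarized at 0.5) plus event accuracy.

    No pre- or post-processing is applied to the predictions. ``model`` may
    be any object exposing ``predict(image) -> (mask, probability)``.
    """
    if not samples:
        raise ValueError("cannot evaluate on an empty sample list")
    dices = []
    preds = []
    targets = []
    for s in samples:
        mask, prob = model.predict(s.image)
        dices.append(dice_coefficient(mask, s.tool_mask))
        preds.append(int(prob >= 0.5))
        targets.append(s.event_label)
    report = classification_accuracy(preds, targets)
    report.dice = float(np.mean(dices))
    return report
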