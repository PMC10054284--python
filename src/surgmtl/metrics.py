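"""Composite multi-task loss and evaluation metrics.

The training objective is the unweighted sum of a per-pixel binary
cross-entropy on the segmentation logits (sigmoid activation) and a
cross-entropy on the event logits (softmax activation):

    loss = segloss + clsloss

Both terms are computed in numerically stable logit form, equivalent to
activation-then-loss, and reduced by the mean over pixels/samples.

Segmentation quality is the Dice coefficient (F1 on pixels),
2·|P∩T| / (|P|+|T|); classification quality is plain accuracy,
#correct / #samples, reported overall and per target class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossBreakdown",
    "MetricReport",
    "multitask_loss",
    "dice_coefficient",
    "classification_accuracy",
]


@dataclass(frozen=True)
class LossBreakdown:
    seg_loss: float
    cls_loss: float
    total: float


@dataclass
class MetricReport:
    """Evaluation summary; ``dice`` is None for classification-only reports."""

    dice: float | None
    accuracy: float
    per_class_accuracy: dict[int, float]
    n_samples: int

    def to_dict(self) -> dict:
        return {
            "dice": self.dice,
            "accuracy": self.accuracy,
            "per_class_accuracy": {str(k): v for k, v in self.per_class_accuracy.items()},
            "n_samples": self.n_samples,
        }


def _bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy in stable logit form, with its gradient."""
    z = np.asarray(logits, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    loss = np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))
    sig = np.empty_like(z)
    pos = z >= 0
    sig[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    sig[~pos] = ez / (1.0 + ez)
    grad = (sig - t) / z.size
    return float(loss.mean()), grad


def _softmax_ce(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy over a (B, C) batch, with gradient."""
    z = np.asarray(logits, dtype=np.float64)
    t = np.asarray(targets)
    zmax = z.max(axis=1, keepdims=True)
    zs = z - zmax
    logsumexp = np.log(np.exp(zs).sum(axis=1))
    b = z.shape[0]
    loss = float((logsumexp - zs[np.arange(b), t]).mean())
    p = np.exp(zs)
    p /= p.sum(axis=1, keepdims=True)
    p[np.arange(b), t] -= 1.0
    return loss, p / b


def multitask_loss(
    seg_logits,
    seg_target,
    event_logits,
    event_target,
    return_grads: bool = False,
):
    """Evaluate the composite objective ``total = seg_loss + cls_loss``.

    Parameters
    ----------
    seg_logits, seg_target
        Same-shaped arrays; targets binary {0, 1}.
    event_logits
        (B, C) array of pre-softmax scores (a single sample may be passed
        as a 1-D array).
    event_target
        Integer class index or (B,) array of indices in [0, C).
    return_grads
        When True also return d(total)/d(seg_logits) and
        d(total)/d(event_logits) for backpropagation.
    """
    seg_logits = np.asarray(seg_logits, dtype=np.float64)
    seg_target = np.asarray(seg_target, dtype=np.float64)
    if seg_logits.shape != seg_target.shape:
        raise ValueError(
            f"seg_logits shape {seg_logits.shape} != seg_target shape {seg_target.shape}"
        )
    event_logits = np.asarray(event_logits, dtype=np.float64)
    if event_logits.ndim == 1:
        event_logits = event_logits[None]
    event_target = np.atleast_1d(np.asarray(event_target, dtype=np.int64))
    if event_target.shape[0] != event_logits.shape[0]:
        raise ValueError("event_target length does not match event_logits batch size")
    n_classes = event_logits.shape[1]
    if event_target.min() < 0 or event_target.max() >= n_classes:
        raise ValueError(
            f"event targets must lie in [0, {n_classes}), got "
            f"[{event_target.min()}, {event_target.max()}]"
        )

    seg_loss, dseg = _bce_with_logits(seg_logits, seg_target)
    cls_loss, dcls = _softmax_ce(event_logits, event_target)
    breakdown = LossBreakdown(seg_loss=seg_loss, cls_loss=cls_loss, total=seg_loss + cls_loss)
    if return_grads:
        return breakdown, dseg, dcls
    return breakdown


def _as_binary_mask(mask, name: str) -> np.ndarray:
    m = np.asarray(mask)
    if m.dtype != bool:
        vals = np.unique(m)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"{name} must be binary with values in {{0, 1}}")
        m = m.astype(bool)
    return m


def dice_coefficient(pred_mask, true_mask) -> float:
    """Dice coefficient 2·|P∩T| / (|P|+|T|) of two binary masks.

    Symmetric in its arguments; 1 means identical masks, 0 disjoint nonempty
    ones. The empty-vs-empty case is 0/0 and is defined here as 1.0 (perfect
    agreement).
    """
    p = _as_binary_mask(pred_mask, "pred_mask")
    t = _as_binary_mask(true_mask, "true_mask")
    if p.shape != t.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {t.shape}")
    overlap = int(np.count_nonzero(p & t))
    total = int(np.count_nonzero(p)) + int(np.count_nonzero(t))
    if total == 0:
        return 1.0
    return 2.0 * overlap / total


def classification_accuracy(predictions, targets) -> MetricReport:
    """Overall and per-class accuracy of predicted class indices.

    Per-class accuracy for class c is computed over the samples whose
    *target* is c.
    """
    pred = np.asarray(predictions, dtype=np.int64).ravel()
    targ = np.asarray(targets, dtype=np.int64).ravel()
    if pred.size == 0:
        raise ValueError("empty input")
    if pred.shape != targ.shape:
        raise ValueError(f"length mismatch: {pred.size} predictions vs {targ.size} targets")
    correct = pred == targ
    per_class: dict[int, float] = {}
    for c in np.unique(targ):
        sel = targ == c
        per_class[int(c)] = float(correct[sel].mean())
    return MetricReport(
        dice=None,
        accuracy=float(correct.mean()),
        per_class_accuracy=per_class,
        n_samples=int(pred.size),
    )
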