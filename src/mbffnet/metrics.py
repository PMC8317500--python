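"""Segmentation evaluation statistics and the Dice + cross-entropy objective.

All statistics are derived from an exact integer confusion matrix
``p[i, j]`` = number of pixels whose true label is ``i`` and predicted
label is ``j``, over ``k + 1`` classes (``k`` foreground classes plus
background as class 0):

* mIOU   — mean over all classes of TP / (TP + FP + FN),
* precision = TP / (TP + FP), recall = TP / (TP + FN) for one class,
* F-score = (1 + beta^2) * P * R / (beta^2 * P + R),
* Dice loss with CE = (1 - 2|y ∩ yhat| / (|y| + |yhat|)) plus the
  per-pixel mean binary cross-entropy.

Degenerate conventions (documented because the ratios are 0/0 there):
a class absent from both prediction and truth contributes IoU 1; absent
from exactly one contributes 0; precision/recall are 0 when their
denominator is 0; the Dice term uses an additive ``eps`` so an all-empty
pair scores ~0 loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EPS = 1e-7

__all__ = [
    "ConfusionCounts",
    "MetricBundle",
    "confusion",
    "miou",
    "precision_recall",
    "f_score",
    "dice_ce_loss",
    "evaluate_pair",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel-level label agreement over k+1 classes (background = 0)."""

    k: int
    p: np.ndarray  # (k+1, k+1) int64, p[i, j] = true i predicted j

    def __post_init__(self):
        if self.p.shape != (self.k + 1, self.k + 1):
            raise ValueError("confusion matrix shape does not match k")
        if (self.p < 0).any():
            raise ValueError("confusion counts must be non-negative")

    def tp(self, i: int) -> int:
        return int(self.p[i, i])

    def fp(self, i: int) -> int:
        return int(self.p[:, i].sum() - self.p[i, i])

    def fn(self, i: int) -> int:
        return int(self.p[i, :].sum() - self.p[i, i])


@dataclass(frozen=True)
class MetricBundle:
    miou: float
    precision: float
    recall: float
    f_score: float
    beta: float
    dice_ce: float


def confusion(pred, truth, k: int = 1) -> ConfusionCounts:
    """Tally the exact (k+1)x(k+1) confusion matrix of two label grids."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    pred = pred.astype(np.int64).ravel()
    truth = truth.astype(np.int64).ravel()
    n = k + 1
    if pred.min(initial=0) < 0 or truth.min(initial=0) < 0:
        raise ValueError("labels must be non-negative")
    if pred.max(initial=0) >= n or truth.max(initial=0) >= n:
        raise ValueError(f"labels must lie in 0..{k}")
    p = np.bincount(truth * n + pred, minlength=n * n).reshape(n, n)
    return ConfusionCounts(k=k, p=p)


def miou(c: ConfusionCounts) -> float:
    """Mean intersection-over-union across all k+1 classes."""
    ious = []
    for i in range(c.k + 1):
        union = c.tp(i) + c.fp(i) + c.fn(i)
        ious.append(1.0 if union == 0 else c.tp(i) / union)
    return float(np.mean(ious))


def precision_recall(c: ConfusionCounts, positive_class: int = 1):
    if not 0 <= positive_class <= c.k:
        raise ValueError(f"positive_class must be in 0..{c.k}")
    tp = c.tp(positive_class)
    fp = c.fp(positive_class)
    fn = c.fn(positive_class)
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    return prec, rec


def f_score(precision: float, recall: float, beta: float = 1.0) -> float:
    if beta <= 0:
        raise ValueError("beta must be positive")
    denom = beta * beta * precision + recall
    if denom == 0:
        return 0.0
    return (1 + beta * beta) * precision * recall / denom


def dice_ce_loss(y, yhat, eps: float = EPS) -> float:
    """Compound objective: (1 - Dice coefficient) + mean binary cross-entropy.

    ``y`` is a binary ground-truth grid, ``yhat`` a probability grid of the
    same shape.  Probabilities are clamped to [eps, 1 - eps] and the Dice
    denominator carries an additive eps.  When the truth has no foreground
    at all the Dice ratio is 0/0; the convention here is to score that
    case by the mean predicted foreground mass, so a correct empty
    prediction costs ~0 and an all-foreground prediction costs ~1.
    """
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: truth {y.shape} vs prediction {yhat.shape}")
    p = np.clip(yhat, eps, 1.0 - eps)
    if y.sum() == 0:
        dice = p.mean()
    else:
        dice = 1.0 - 2.0 * (y * p).sum() / (y.sum() + p.sum() + eps)
    ce = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).mean()
    return float(dice + ce)


def evaluate_pair(pred_mask, truth_mask, prob=None, beta: float = 1.0) -> MetricBundle:
    """All binary-segmentation metrics for one predicted/true mask pair.

    ``prob`` (optional) supplies the raw probability map for the Dice+CE
    term; when omitted the hard mask is used in its place.
    """
    c = confusion(pred_mask, truth_mask, k=1)
    prec, rec = precision_recall(c, positive_class=1)
    p = np.asarray(pred_mask, dtype=np.float64) if prob is None else prob
    return MetricBundle(
        miou=miou(c),
        precision=prec,
        recall=rec,
        f_score=f_score(prec, rec, beta),
        beta=beta,
        dice_ce=dice_ce_loss(np.asarray(truth_mask), p),
    )
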