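"""Training and evaluation loops (Adam on the Dice + cross-entropy loss)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np

from . import metrics, nn
from .data import AugmentationConfig, SegmentationSample, augment
from .metrics import EPS
from .nn import Var

__all__ = ["TrainConfig", "dice_ce_objective", "train", "evaluate", "overlay"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings.  Adam with a fixed learning rate of 0.001
    is the published recipe; batch size and epoch count are free
    experiment choices."""

    learning_rate: float = 1e-3
    batch_size: int = 8
    epochs: int = 10
    seed: int = 0
    augmentation: Optional[AugmentationConfig] = field(default_factory=AugmentationConfig)
    checkpoint_path: Optional[str] = None

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def dice_ce_objective(prob: Var, truth: np.ndarray) -> Var:
    """Differentiable Dice + mean-CE loss over a batch.

    Numerically identical to :func:`mbffnet.metrics.dice_ce_loss` on the
    same arrays (up to float32 rounding); the sums run over the whole
    batch so every image contributes to one global Dice term.
    """
    y = np.asarray(truth, dtype=np.float32)
    if y.shape != prob.shape:
        raise ValueError(f"shape mismatch: truth {y.shape} vs prediction {prob.shape}")
    p = nn.clip(prob, EPS, 1.0 - EPS)
    if y.sum() == 0:  # empty-truth convention, see metrics.dice_ce_loss
        dice = nn.vmean(p)
    else:
        inter = nn.vsum(p * y)
        dice = 1.0 - (2.0 * inter) / (float(y.sum()) + nn.vsum(p) + EPS)
    ce = -nn.vmean(y * nn.log(p) + (1.0 - y) * nn.log(1.0 - p))
    return dice + ce


def _batch_arrays(samples: Sequence[SegmentationSample]):
    x = np.stack([s.image.transpose(2, 0, 1) for s in samples])
    y = np.stack([s.mask[None].astype(np.float32) for s in samples])
    return x, y


def train(
    model,
    train_samples: Sequence[SegmentationSample],
    val_samples: Sequence[SegmentationSample] = (),
    config: TrainConfig = None,
) -> dict:
    """Mini-batch Adam optimisation of the Dice+CE objective.

    Samples are augmented per epoch with seeds derived from
    ``config.seed``, so a run is fully deterministic.  Returns a log with
    per-epoch mean training loss and (if ``val_samples``) validation mIOU.
    """
    config = config or TrainConfig()
    if not train_samples:
        raise ValueError("empty training set")
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    log = {"train_loss": [], "val_miou": []}
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_samples))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = []
            for i in idx:
                s = train_samples[i]
                if config.augmentation is not None:
                    s = augment(s, config.augmentation, seed=int(rng.integers(2**31 - 1)))
                batch.append(s)
            x, y = _batch_arrays(batch)
            prob = model.forward(Var(x))
            loss = dice_ce_objective(prob, y)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        log["train_loss"].append(float(np.mean(losses)))
        if val_samples:
            log["val_miou"].append(evaluate(model, val_samples)["mean"]["miou"])
    if config.checkpoint_path:
        model.save_weights(config.checkpoint_path)
    return log


def evaluate(
    model,
    samples: Sequence[SegmentationSample],
    threshold: float = 0.5,
    beta: float = 1.0,
) -> dict:
    """Per-image and mean mIOU / F-score / Dice+CE over a sample set."""
    if not samples:
        raise ValueError("empty evaluation set")
    per_image = []
    for s in samples:
        prob, pred = model.predict(s.image, threshold=threshold)
        bundle = metrics.evaluate_pair(pred, s.mask, prob=prob, beta=beta)
        per_image.append(
            {
                "miou": bundle.miou,
                "precision": bundle.precision,
                "recall": bundle.recall,
                "f_score": bundle.f_score,
                "dice_ce": bundle.dice_ce,
            }
        )
    mean = {
        k: float(np.mean([r[k] for r in per_image])) for k in per_image[0]
    }
    return {"per_image": per_image, "mean": mean}


def overlay(pred_mask: np.ndarray, truth_mask: np.ndarray) -> np.ndarray:
    """TP/FP/FN colour overlay (HxWx3 uint8): red = true positive,
    blue = false positive, green = false negative."""
    pred = np.asarray(pred_mask).astype(bool)
    truth = np.asarray(truth_mask).astype(bool)
    img = np.zeros(pred.shape + (3,), dtype=np.uint8)
    img[pred & truth] = (255, 0, 0)
    img[pred & ~truth] = (0, 0, 255)
    img[~pred & truth] = (0, 255, 0)
    return img


def write_metrics(result: dict, path):
    """JSON metric table plus a CSV mirror of the mean row."""
    path = Path(path)
    path.write_text(json.dumps(result, indent=1))
    csv_path = path.with_suffix(".csv")
    keys = list(result["mean"].keys())
    lines = [",".join(["image"] + keys)]
    for i, row in enumerate(result["per_image"]):
        lines.append(",".join([str(i)] + [f"{row[k]:.6f}" for k in keys]))
    lines.append(",".join(["mean"] + [f"{result['mean'][k]:.6f}" for k in keys]))
    csv_path.write_text("\n".join(lines) + "\n")
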