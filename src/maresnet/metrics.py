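"""Segmentation metrics (precision / recall / IoU / F1 over pixel confusion
counts) and the smoothed Dice training loss.

Degenerate-denominator convention: when both masks are empty the prediction
is perfect, so every metric returns 1; when only the denominator of a single
metric vanishes (e.g. no predicted positives) it returns 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DICE_EPS = 1.0  # smoothing term of the Dice loss

AGGREGATIONS = ("per_image_mean", "global_pool")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    precision: float
    recall: float
    iou: float
    f1: float
    n_images: int
    aggregation: str = "per_image_mean"

    def as_percent_dict(self, decimals: int = 2) -> dict:
        """Table-style view: percentages rounded to ``decimals`` places."""
        return {
            "precision": round(100 * self.precision, decimals),
            "recall": round(100 * self.recall, decimals),
            "iou": round(100 * self.iou, decimals),
            "f1": round(100 * self.f1, decimals),
            "n_images": self.n_images,
            "aggregation": self.aggregation,
        }


def _check_binary(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a)
    vals = np.unique(a)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1); found values {vals[:5]}")
    return a.astype(bool)


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Exact TP/FP/FN/TN pixel tallies for a binary mask pair."""
    pred = _check_binary(pred, "pred")
    truth = _check_binary(truth, "truth")
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    tn = int((~pred & ~truth).sum())
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: int, den: int, c: ConfusionCounts) -> float:
    if den == 0:
        # no positives anywhere in play: empty-vs-empty counts as perfect
        return 1.0 if (c.tp + c.fp + c.fn) == 0 else 0.0
    return num / den


def precision(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fp, c)


def recall(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fn, c)


def iou(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fp + c.fn, c)


def f1(c: ConfusionCounts) -> float:
    p, r = precision(c), recall(c)
    if p + r == 0:
        return 1.0 if (c.tp + c.fp + c.fn) == 0 else 0.0
    return 2 * p * r / (p + r)


def metrics_from_counts(c: ConfusionCounts, n_images: int = 1,
                        aggregation: str = "global_pool") -> MetricsReport:
    return MetricsReport(precision(c), recall(c), iou(c), f1(c),
                         n_images=n_images, aggregation=aggregation)


def dice_loss(prob: np.ndarray, truth: np.ndarray,
              eps: float = DICE_EPS) -> float:
    """1 - (2*sum(p*g) + eps) / (sum(p) + sum(g) + eps)."""
    prob = np.asarray(prob, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if prob.shape != truth.shape:
        raise ValueError(f"shape mismatch: prob {prob.shape} vs truth {truth.shape}")
    inter = float((prob * truth).sum())
    return 1.0 - (2.0 * inter + eps) / (float(prob.sum()) + float(truth.sum()) + eps)


def dice_loss_grad(prob: np.ndarray, truth: np.ndarray,
                   eps: float = DICE_EPS) -> np.ndarray:
    """d(dice_loss)/d(prob), same shape as ``prob``."""
    prob = np.asarray(prob, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    a = 2.0 * float((prob * truth).sum()) + eps
    b = float(prob.sum()) + float(truth.sum()) + eps
    return (-(2.0 * truth * b - a) / (b * b)).astype(prob.dtype)


def evaluate_masks(pred_probs: list[np.ndarray], truths: list[np.ndarray],
                   threshold: float = 0.5,
                   aggregation: str = "per_image_mean") -> MetricsReport:
    """Binarise probability maps at ``threshold`` and aggregate metrics.

    ``per_image_mean`` averages each metric over images (table convention);
    ``global_pool`` sums confusion counts over the whole set first, under
    which F1 is exactly the harmonic mean of the pooled P and R.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if aggregation not in AGGREGATIONS:
        raise ValueError(f"aggregation must be one of {AGGREGATIONS}")
    if len(pred_probs) == 0:
        raise ValueError("empty sample list")
    counts = [confusion_counts((np.asarray(p) >= threshold).astype(np.uint8),
                               np.asarray(t)) for p, t in zip(pred_probs, truths)]
    n = len(counts)
    if aggregation == "global_pool":
        pooled = counts[0]
        for c in counts[1:]:
            pooled = pooled + c
        return metrics_from_counts(pooled, n_images=n, aggregation=aggregation)
    reports = [metrics_from_counts(c) for c in counts]
    return MetricsReport(
        float(np.mean([r.precision for r in reports])),
        float(np.mean([r.recall for r in reports])),
        float(np.mean([r.iou for r in reports])),
        float(np.mean([r.f1 for r in reports])),
        n_images=n, aggregation=aggregation)


def evaluate_dataset(model, samples, threshold: float = 0.5,
                     aggregation: str = "per_image_mean") -> MetricsReport:
    """Run ``model`` (a callable image -> probability map, e.g. a trained
    network's predict function) over ImageSamples and aggregate metrics."""
    if len(samples) == 0:
        raise ValueError("empty sample list")
    probs, truths = [], []
    for s in samples:
        probs.append(np.asarray(model(s.image)).squeeze())
        truths.append(s.mask)
    return evaluate_masks(probs, truths, threshold, aggregation)
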