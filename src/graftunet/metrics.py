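"""Confusion-count segmentation metrics.

Six metrics are derived from per-pixel confusion counts of a
thresholded probability map against a binary ground-truth mask:

    Dice      = 2*tp / (2*tp + fp + fn)
    IoU       = tp / (tp + fp + fn)
    Recall    = tp / (tp + fn)
    Precision = tp / (tp + fp)
    F2        = 5*p*r / (4*p + r)
    Accuracy  = (tp + tn) / (tp + tn + fp + fn)

Zero denominators follow the vacuous-truth convention: a metric whose
denominator is empty scores 1.0 when the prediction agrees with the
truth everywhere (fp = fn = 0) and 0.0 otherwise, which keeps
all-background frames scoreable.

Set-level evaluation offers two aggregations: ``per_image_mean``
(each metric computed per image, then averaged — what a reported
"mean Dice" usually denotes) and ``global_counts`` (metrics of the
pooled confusion counts, under which Dice = 2*IoU/(1+IoU) holds as an
exact identity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_from_masks",
    "dice",
    "iou",
    "recall",
    "precision",
    "f2",
    "accuracy",
    "metrics_from_counts",
    "evaluate_set",
    "evaluate_both",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel confusion counts; tp+fp+fn+tn is the number of evaluated pixels."""

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

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


@dataclass(frozen=True)
class MetricReport:
    """The six metrics in [0, 1] plus the aggregation that produced them."""

    mdice: float
    miou: float
    recall: float
    precision: float
    f2: float
    accuracy: float
    aggregation: str  # "per_image_mean" | "global_counts"

    def as_dict(self) -> dict:
        return {
            "mdice": self.mdice,
            "miou": self.miou,
            "recall": self.recall,
            "precision": self.precision,
            "f2": self.f2,
            "accuracy": self.accuracy,
            "aggregation": self.aggregation,
        }


def confusion_from_masks(pred, gt, threshold: float = 0.5) -> ConfusionCounts:
    """Count tp/fp/fn/tn of ``pred >= threshold`` against a binary mask."""
    p = np.asarray(pred)
    g = np.asarray(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    gset = np.unique(g)
    if not np.all(np.isin(gset, (0, 1))):
        raise ValueError("ground-truth mask must be strictly binary (0/1)")
    pb = p >= threshold
    gb = g.astype(bool)
    tp = int(np.count_nonzero(pb & gb))
    fp = int(np.count_nonzero(pb & ~gb))
    fn = int(np.count_nonzero(~pb & gb))
    tn = int(np.count_nonzero(~pb & ~gb))
    return ConfusionCounts(tp, fp, fn, tn)


def _vacuous(c: ConfusionCounts) -> float:
    return 1.0 if (c.fp == 0 and c.fn == 0) else 0.0


def dice(c: ConfusionCounts) -> float:
    d = 2 * c.tp + c.fp + c.fn
    return 2 * c.tp / d if d else _vacuous(c)


def iou(c: ConfusionCounts) -> float:
    d = c.tp + c.fp + c.fn
    return c.tp / d if d else _vacuous(c)


def recall(c: ConfusionCounts) -> float:
    d = c.tp + c.fn
    return c.tp / d if d else _vacuous(c)


def precision(c: ConfusionCounts) -> float:
    d = c.tp + c.fp
    return c.tp / d if d else _vacuous(c)


def f2(c: ConfusionCounts) -> float:
    """Recall-weighted F-score, F2 = 5*p*r / (4*p + r)."""
    p, r = precision(c), recall(c)
    d = 4 * p + r
    return 5 * p * r / d if d else _vacuous(c)


def accuracy(c: ConfusionCounts) -> float:
    return (c.tp + c.tn) / c.total if c.total else _vacuous(c)


def metrics_from_counts(c: ConfusionCounts, aggregation: str = "global_counts") -> MetricReport:
    return MetricReport(
        mdice=dice(c),
        miou=iou(c),
        recall=recall(c),
        precision=precision(c),
        f2=f2(c),
        accuracy=accuracy(c),
        aggregation=aggregation,
    )


def evaluate_set(
    pred_masks: Sequence,
    gt_masks: Sequence,
    threshold: float = 0.5,
    aggregation: str = "per_image_mean",
) -> MetricReport:
    """Evaluate a paired set of probability maps and binary masks.

    ``per_image_mean`` averages each metric over images;
    ``global_counts`` pools all pixels first.
    """
    if len(pred_masks) != len(gt_masks):
        raise ValueError("pred and gt lists must have equal length")
    if len(pred_masks) == 0:
        raise ValueError("cannot evaluate an empty set")
    counts = [confusion_from_masks(p, g, threshold) for p, g in zip(pred_masks, gt_masks)]
    if aggregation == "global_counts":
        pooled = counts[0]
        for c in counts[1:]:
            pooled = pooled + c
        return metrics_from_counts(pooled, "global_counts")
    if aggregation != "per_image_mean":
        raise ValueError(f"unknown aggregation {aggregation!r}")
    reports = [metrics_from_counts(c) for c in counts]
    mean = lambda key: float(np.mean([getattr(r, key) for r in reports]))  # noqa: E731
    return MetricReport(
        mdice=mean("mdice"),
        miou=mean("miou"),
        recall=mean("recall"),
        precision=mean("precision"),
        f2=mean("f2"),
        accuracy=mean("accuracy"),
        aggregation="per_image_mean",
    )


def evaluate_both(pred_masks, gt_masks, threshold: float = 0.5) -> dict:
    """Both aggregation modes, as a JSON-ready dict."""
    return {
        "per_image_mean": evaluate_set(pred_masks, gt_masks, threshold, "per_image_mean").as_dict(),
        "global_counts": evaluate_set(pred_masks, gt_masks, threshold, "global_counts").as_dict(),
    }
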