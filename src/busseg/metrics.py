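"""Segmentation evaluation metrics for binary lesion masks.

All metrics are computed from per-pixel confusion counts against a gold
standard with label 1 = lesion (positive class) and label 0 =
background: global accuracy, per-class mean accuracy, per-class and
mean IoU (Jaccard), frequency-weighted IoU, Dice similarity, and the
Boundary F1 (BF) score which matches predicted and gold boundary pixels
within a Euclidean distance tolerance.

Degenerate cases (an empty class making a denominator zero) yield NaN —
a flagged missing value — rather than an arbitrary 0 or 1, and are
skipped when averaging over an image set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "accuracy_metrics",
    "iou_metrics",
    "dice",
    "bf_score",
    "boundary_pixels",
    "default_bf_tolerance",
    "overlay_errors",
    "evaluate_pair",
    "evaluate_set",
]

# Fig.-7-style overlay palette (RGB)
_COLOR_TP = (255, 255, 255)  # white
_COLOR_TN = (0, 0, 0)        # black
_COLOR_FP = (255, 105, 180)  # pink
_COLOR_FN = (0, 200, 0)      # green


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies of a prediction against the gold standard."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"{f.name} must be >= 0, got {v}")


@dataclass(frozen=True)
class MetricReport:
    """The full metric suite for one prediction/gold pair.

    NaN fields mark metrics undefined on this pair (e.g. mean accuracy
    when the gold mask has no lesion pixels).
    """

    global_accuracy: float
    mean_accuracy: float
    iou_lesion: float
    iou_background: float
    mean_iou: float
    weighted_iou: float
    dice: float
    bf_score: float
    lesion_weight: float
    background_weight: float


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must contain only labels 0 and 1")
    return arr.astype(bool)


def confusion_counts(pred: np.ndarray, gold: np.ndarray) -> ConfusionCounts:
    """Per-pixel confusion tallies; label 1 (lesion) is the positive class."""
    pred = np.asarray(pred)
    gold = np.asarray(gold)
    if pred.shape != gold.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gold {gold.shape}")
    p = _check_binary(pred, "pred")
    g = _check_binary(gold, "gold")
    return ConfusionCounts(
        tp=int(np.sum(p & g)),
        fp=int(np.sum(p & ~g)),
        fn=int(np.sum(~p & g)),
        tn=int(np.sum(~p & ~g)),
    )


def accuracy_metrics(c: ConfusionCounts) -> tuple[float, float]:
    """(global accuracy, mean per-class accuracy).

    Global accuracy is the fraction of all pixels correctly classified;
    mean accuracy averages lesion recall and background recall.  If a
    class is absent from the gold standard its recall — and hence the
    mean — is NaN.
    """
    if c.total == 0:
        raise ValueError("no pixels to evaluate")
    global_acc = (c.tp + c.tn) / c.total
    pos, neg = c.tp + c.fn, c.tn + c.fp
    if pos == 0 or neg == 0:
        mean_acc = math.nan
    else:
        mean_acc = (c.tp / pos + c.tn / neg) / 2.0
    return global_acc, mean_acc


def iou_metrics(
    c: ConfusionCounts,
) -> tuple[float, float, float, float, float, float]:
    """Per-class, mean and frequency-weighted Jaccard indices.

    Returns (iou_lesion, iou_background, mean_iou, weighted_iou,
    lesion_weight, background_weight).  Class weights are the gold-mask
    class proportions and always sum to 1.
    """
    if c.total == 0:
        raise ValueError("no pixels to evaluate")
    denom_l = c.tp + c.fn + c.fp
    denom_b = c.tn + c.fn + c.fp
    iou_l = c.tp / denom_l if denom_l > 0 else math.nan
    iou_b = c.tn / denom_b if denom_b > 0 else math.nan
    mean_iou = (iou_l + iou_b) / 2.0  # NaN propagates
    w_l = (c.tp + c.fn) / c.total
    w_b = (c.tn + c.fp) / c.total
    weighted = w_l * iou_l + w_b * iou_b
    return iou_l, iou_b, mean_iou, weighted, w_l, w_b


def dice(c: ConfusionCounts) -> float:
    """Dice similarity coefficient 2TP / (2TP + FN + FP); NaN when both
    masks are empty."""
    denom = 2 * c.tp + c.fn + c.fp
    if denom == 0:
        return math.nan
    return 2 * c.tp / denom


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Boundary of the lesion class under 4-connectivity.

    A lesion pixel is boundary if any 4-neighbour is background or lies
    outside the image.
    """
    m = _check_binary(np.asarray(mask), "mask")
    padded = np.pad(m, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return m & ~interior


def default_bf_tolerance(shape: tuple[int, int]) -> int:
    """0.75% of the image diagonal, rounded up — the conventional BF
    match tolerance when none is specified."""
    diag = math.hypot(*shape)
    return math.ceil(0.0075 * diag)


def bf_score(
    pred: np.ndarray, gold: np.ndarray, tolerance_px: int | None = None
) -> float:
    """Boundary F1 score: harmonic mean of boundary precision and recall.

    Precision is the fraction of predicted-boundary pixels within
    ``tolerance_px`` (Euclidean) of some gold-boundary pixel; recall is
    symmetric.  Returns 0 when precision + recall is 0 but one boundary
    exists, NaN when both boundaries are empty.
    """
    pred = np.asarray(pred)
    gold = np.asarray(gold)
    if pred.shape != gold.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gold {gold.shape}")
    if tolerance_px is None:
        tolerance_px = default_bf_tolerance(pred.shape)
    if tolerance_px < 0:
        raise ValueError("tolerance_px must be >= 0")
    bp = boundary_pixels(pred)
    bg = boundary_pixels(gold)
    if not bp.any() and not bg.any():
        return math.nan
    if not bp.any() or not bg.any():
        return 0.0
    dist_to_gold = distance_transform_edt(~bg)
    dist_to_pred = distance_transform_edt(~bp)
    precision = float(np.mean(dist_to_gold[bp] <= tolerance_px))
    recall = float(np.mean(dist_to_pred[bg] <= tolerance_px))
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def overlay_errors(pred: np.ndarray, gold: np.ndarray) -> np.ndarray:
    """RGB error overlay: FP pink, FN green, TP white, TN black."""
    pred = np.asarray(pred)
    gold = np.asarray(gold)
    if pred.shape != gold.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gold {gold.shape}")
    p = _check_binary(pred, "pred")
    g = _check_binary(gold, "gold")
    out = np.zeros(pred.shape + (3,), dtype=np.uint8)
    out[p & g] = _COLOR_TP
    out[~p & ~g] = _COLOR_TN
    out[p & ~g] = _COLOR_FP
    out[~p & g] = _COLOR_FN
    return out


def evaluate_pair(
    pred: np.ndarray, gold: np.ndarray, tolerance_px: int | None = None
) -> MetricReport:
    """Compute the full MetricReport for one prediction/gold pair."""
    c = confusion_counts(pred, gold)
    global_acc, mean_acc = accuracy_metrics(c)
    iou_l, iou_b, mean_iou, weighted, w_l, w_b = iou_metrics(c)
    return MetricReport(
        global_accuracy=global_acc,
        mean_accuracy=mean_acc,
        iou_lesion=iou_l,
        iou_background=iou_b,
        mean_iou=mean_iou,
        weighted_iou=weighted,
        dice=dice(c),
        bf_score=bf_score(pred, gold, tolerance_px),
        lesion_weight=w_l,
        background_weight=w_b,
    )


def evaluate_set(
    pairs: list[tuple[np.ndarray, np.ndarray]],
    tolerance_px: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate a list of (pred, gold) pairs.

    Returns (per_image, summary): per_image has one MetricReport row per
    pair; summary holds the per-metric mean and sample standard
    deviation over images, skipping NaN (undefined) values.  With one
    image, or one defined value, the std is NaN.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one (pred, gold) pair")
    rows = [evaluate_pair(p, g, tolerance_px) for p, g in pairs]
    per_image = pd.DataFrame([r.__dict__ for r in rows])
    summary = pd.DataFrame(
        {"mean": per_image.mean(skipna=True), "std": per_image.std(ddof=1, skipna=True)}
    )
    return per_image, summary
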