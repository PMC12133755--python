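"""Detection/segmentation evaluation: matching, P, R, AP, mAP, ratio errors.

Matching follows the greedy confidence-ordered protocol standard for
single-stage detector evaluation: predictions are visited in descending
confidence (ties broken by input order); each claims the unmatched ground
truth of highest IoU if that IoU clears the threshold, otherwise it is a
false positive; leftover truths are false negatives.

AP is the area under the precision-recall curve over confidence prefixes.
The default integration applies the all-point precision envelope (each
recall level gets the maximum precision attained at any recall >= it);
101-point interpolation is available for comparability with COCO-style
tooling. mAP averages class APs; with a single class mAP equals AP.
mAP@0.5:0.95 averages AP over IoU thresholds 0.50 to 0.95 in steps of 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Assignment",
    "MatchTable",
    "PRCurve",
    "ErrorMetrics",
    "match_predictions",
    "precision_recall",
    "pr_curve",
    "average_precision",
    "mean_average_precision",
    "map_range",
    "error_metrics",
    "MAP_RANGE_THRESHOLDS",
]

MAP_RANGE_THRESHOLDS: tuple[float, ...] = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


@dataclass(frozen=True)
class Assignment:
    pred_id: int
    truth_id: int | None
    confidence: float
    is_tp: bool


@dataclass
class MatchTable:
    """TP/FP/FN assignment of predictions to ground truths at one IoU cut."""

    iou_threshold: float
    assignments: list[Assignment]
    n_truths: int

    @property
    def tp(self) -> int:
        return sum(a.is_tp for a in self.assignments)

    @property
    def fp(self) -> int:
        return sum(not a.is_tp for a in self.assignments)

    @property
    def fn(self) -> int:
        return self.n_truths - self.tp


def match_predictions(
    preds: Sequence[tuple[object, float]],
    truths: Sequence[object],
    iou_fn: Callable[[object, object], float],
    threshold: float,
) -> MatchTable:
    """Greedy confidence-ordered one-to-one matching.

    ``preds`` is a sequence of (object, confidence); ``iou_fn`` computes
    overlap between a prediction object and a truth object (mask or box IoU).
    """
    order = sorted(range(len(preds)), key=lambda i: -preds[i][1])
    taken = [False] * len(truths)
    assignments: list[Assignment] = []
    for i in order:
        obj, conf = preds[i]
        best_j, best_iou = None, 0.0
        for j, t in enumerate(truths):
            if taken[j]:
                continue
            iou = iou_fn(obj, t)
            if iou > best_iou:
                best_j, best_iou = j, iou
        if best_j is not None and best_iou >= threshold:
            taken[best_j] = True
            assignments.append(Assignment(i, best_j, conf, True))
        else:
            assignments.append(Assignment(i, None, conf, False))
    return MatchTable(threshold, assignments, len(truths))


def precision_recall(table: MatchTable) -> tuple[float, float]:
    """(P, R) with the conventions P=1 for no predictions, R=1 for no truths."""
    n_pred = len(table.assignments)
    p = table.tp / n_pred if n_pred else 1.0
    r = table.tp / table.n_truths if table.n_truths else 1.0
    return p, r


@dataclass
class PRCurve:
    """Precision-recall points over descending-confidence prefixes."""

    recall: np.ndarray
    precision: np.ndarray
    ap: float


def _prefix_curve(table: MatchTable) -> tuple[np.ndarray, np.ndarray]:
    """Recall/precision at every descending-confidence prefix."""
    flags = np.array(
        [a.is_tp for a in sorted(table.assignments, key=lambda a: -a.confidence)],
        dtype=float,
    )
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(1.0 - flags)
    recall = tp_cum / table.n_truths if table.n_truths else np.ones_like(tp_cum)
    precision = tp_cum / (tp_cum + fp_cum)
    return recall, precision


def pr_curve(
    preds, truths, iou_fn, threshold: float, interpolation: str = "envelope"
) -> PRCurve:
    table = match_predictions(preds, truths, iou_fn, threshold)
    if not truths:
        ap = 1.0 if not preds else 0.0
        return PRCurve(np.array([]), np.array([]), ap)
    if not preds:
        return PRCurve(np.array([0.0]), np.array([1.0]), 0.0)
    recall, precision = _prefix_curve(table)
    ap = _integrate(recall, precision, interpolation)
    return PRCurve(recall, precision, ap)


def _integrate(recall: np.ndarray, precision: np.ndarray, interpolation: str) -> float:
    # Precision envelope: max precision at any recall >= r.
    env = np.maximum.accumulate(precision[::-1])[::-1]
    if interpolation == "envelope":
        r_prev = np.concatenate([[0.0], recall[:-1]])
        return float(np.sum((recall - r_prev) * env))
    if interpolation == "101point":
        grid = np.linspace(0.0, 1.0, 101)
        # For each grid recall, the envelope precision at the first curve
        # point with recall >= it (0 beyond the max attained recall).
        idx = np.searchsorted(recall, grid, side="left")
        vals = np.where(idx < len(recall), env[np.minimum(idx, len(recall) - 1)], 0.0)
        return float(vals.mean())
    raise ValueError(f"unknown interpolation {interpolation!r}")


def average_precision(
    preds, truths, iou_fn, threshold: float, interpolation: str = "envelope"
) -> float:
    """Area under the PR curve for one class at one IoU threshold."""
    return pr_curve(preds, truths, iou_fn, threshold, interpolation).ap


def mean_average_precision(per_class_aps: Sequence[float]) -> float:
    """Arithmetic mean of class APs (with one class, mAP = AP)."""
    if len(per_class_aps) == 0:
        raise ValueError("mAP over zero classes is undefined")
    return float(np.mean(per_class_aps))


def map_range(
    preds,
    truths,
    iou_fn,
    thresholds: Sequence[float] = MAP_RANGE_THRESHOLDS,
    interpolation: str = "envelope",
) -> float:
    """Mean AP across an IoU-threshold sweep (default 0.50:0.05:0.95)."""
    return float(
        np.mean([average_precision(preds, truths, iou_fn, t, interpolation) for t in thresholds])
    )


@dataclass
class ErrorMetrics:
    """Pointwise regression-style errors between predicted and true ratios.

    ``mape_percent`` is reported in percent and excludes samples whose true
    value is zero; ``n_excluded_zero_truth`` counts them.
    """

    rmse: float
    mae: float
    mape_percent: float
    n: int
    n_excluded_zero_truth: int


def error_metrics(predicted: Sequence[float], truth: Sequence[float]) -> ErrorMetrics:
    predicted = np.asarray(predicted, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predicted.shape != truth.shape or predicted.ndim != 1 or len(predicted) < 1:
        raise ValueError("predicted and truth must be equal-length 1-D, n >= 1")
    diff = predicted - truth
    rmse = float(np.sqrt(np.mean(diff**2)))
    mae = float(np.mean(np.abs(diff)))
    nonzero = truth != 0
    n_excl = int(np.count_nonzero(~nonzero))
    if not nonzero.any():
        raise ValueError("MAPE undefined: every ground-truth value is zero")
    mape = float(np.mean(np.abs(diff[nonzero] / truth[nonzero])) * 100.0)
    return ErrorMetrics(rmse, mae, mape, len(predicted), n_excl)
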