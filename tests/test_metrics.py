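"""Matching, precision/recall, AP/mAP, and ratio error metrics.

The AP oracle is an independent brute-force route: re-match every
descending-confidence prefix from scratch, read off (recall, precision)
per prefix, and integrate the precision envelope directly.
"""

import numpy as np
import pytest

from berrybruise.metrics import (
    MAP_RANGE_THRESHOLDS,
    ErrorMetrics,
    average_precision,
    error_metrics,
    map_range,
    match_predictions,
    mean_average_precision,
    precision_recall,
)
from berrybruise.raster_core import BoundingBox, box_iou, mask_iou


def brute_force_ap(preds, truths, iou_fn, threshold):
    """Exhaustive prefix enumeration with independent per-prefix matching."""
    if not truths:
        return 1.0 if not preds else 0.0
    order = sorted(range(len(preds)), key=lambda i: -preds[i][1])
    points = []
    for k in range(1, len(order) + 1):
        prefix = [preds[i] for i in order[:k]]
        # independent greedy matching of the prefix
        taken = set()
        tp = 0
        for obj, _ in prefix:
            best_j, best = None, 0.0
            for j, t in enumerate(truths):
                if j in taken:
                    continue
                v = iou_fn(obj, t)
                if v > best:
                    best_j, best = j, v
            if best_j is not None and best >= threshold:
                taken.add(best_j)
                tp += 1
        points.append((tp / len(truths), tp / k))
    ap, r_prev = 0.0, 0.0
    for i, (r, _) in enumerate(points):
        p_env = max(p for _, p in points[i:])
        ap += (r - r_prev) * p_env
        r_prev = r
    return ap


def _interval_iou(a, b):
    """IoU of 1-D integer intervals, a cheap stand-in geometry."""
    lo = max(a[0], b[0])
    hi = min(a[1], b[1])
    inter = max(hi - lo, 0)
    union = (a[1] - a[0]) + (b[1] - b[0]) - inter
    return inter / union if union else 0.0


class TestMatching:
    def test_perfect_single_match(self):
        t = BoundingBox(0, 0, 10, 10)
        table = match_predictions([(t, 0.9)], [t], box_iou, 0.5)
        assert (table.tp, table.fp, table.fn) == (1, 0, 0)

    def test_duplicate_prediction_counts_one_fp(self):
        t = BoundingBox(0, 0, 10, 10)
        table = match_predictions([(t, 0.9), (t, 0.8)], [t], box_iou, 0.5)
        assert (table.tp, table.fp, table.fn) == (1, 1, 0)

    def test_counts_partition_predictions_and_truths(self):
        rng = np.random.default_rng(3)
        truths = [(int(s), int(s) + 10) for s in rng.integers(0, 80, 5)]
        preds = [((int(s), int(s) + 10), float(c))
                 for s, c in zip(rng.integers(0, 80, 8), rng.random(8))]
        table = match_predictions(preds, truths, _interval_iou, 0.3)
        assert table.tp + table.fp == len(preds)
        assert table.tp + table.fn == len(truths)

    def test_greedy_matches_exhaustive_on_crafted_table(self):
        # 3 preds / 3 truths with a crafted overlap structure: the
        # confidence-ordered greedy assignment is unique and checkable.
        truths = [(0, 10), (20, 30), (40, 50)]
        preds = [((21, 31), 0.95), ((0, 10), 0.9), ((22, 32), 0.85)]
        table = match_predictions(preds, truths, _interval_iou, 0.5)
        flags = {a.pred_id: a.is_tp for a in table.assignments}
        assert flags == {0: True, 1: True, 2: False}


class TestPrecisionRecall:
    def test_formula(self):
        t = BoundingBox(0, 0, 5, 5)
        far = BoundingBox(50, 50, 55, 55)
        preds = [(t, 0.9)] * 8 + [(far, 0.8)] * 2
        truths = [t] * 8 + [BoundingBox(80, 80, 85, 85)] * 2
        # engineered counts: 8 TP (one per identical truth), 2 FP, 2 FN
        table = match_predictions(preds, truths, box_iou, 0.5)
        p, r = precision_recall(table)
        assert (p, r) == (0.8, 0.8)

    def test_conventions(self):
        empty = match_predictions([], [BoundingBox(0, 0, 1, 1)] * 5, box_iou, 0.5)
        assert precision_recall(empty) == (1.0, 0.0)
        nothing = match_predictions([], [], box_iou, 0.5)
        assert precision_recall(nothing) == (1.0, 1.0)


class TestAveragePrecision:
    def test_single_perfect_prediction(self):
        t = BoundingBox(0, 0, 10, 10)
        assert average_precision([(t, 0.9)], [t], box_iou, 0.5) == 1.0

    def test_fp_before_tp_halves_ap(self):
        # FP at 0.9 then TP at 0.8 on one truth: curve (0, 0), (1, 0.5);
        # all-point envelope integrates to 0.5.
        truth = BoundingBox(0, 0, 10, 10)
        far = BoundingBox(50, 50, 60, 60)
        preds = [(far, 0.9), (truth, 0.8)]
        assert average_precision(preds, [truth], box_iou, 0.5) == pytest.approx(0.5)
        assert brute_force_ap(preds, [truth], box_iou, 0.5) == pytest.approx(0.5)

    def test_zero_truth_conventions(self):
        assert average_precision([], [], box_iou, 0.5) == 1.0
        assert average_precision([(BoundingBox(0, 0, 1, 1), 0.5)], [], box_iou, 0.5) == 0.0

    @pytest.mark.parametrize("seed", range(60))
    def test_matches_exhaustive_prefix_oracle(self, seed):
        # >= 50 random instances with <= 6 predictions on a 1-D geometry.
        rng = np.random.default_rng(seed)
        n_t = int(rng.integers(1, 5))
        n_p = int(rng.integers(0, 7))
        truths = [(int(s), int(s) + int(rng.integers(5, 15)))
                  for s in rng.integers(0, 60, n_t)]
        preds = [
            ((int(s), int(s) + int(rng.integers(5, 15))), float(np.round(c, 3)))
            for s, c in zip(rng.integers(0, 60, n_p), rng.random(n_p))
        ]
        thr = float(rng.choice([0.3, 0.5, 0.7]))
        got = average_precision(preds, truths, _interval_iou, thr)
        want = brute_force_ap(preds, truths, _interval_iou, thr)
        assert got == pytest.approx(want, abs=1e-12)

    def test_invariant_to_uniform_confidence_rescaling(self):
        rng = np.random.default_rng(11)
        truths = [(int(s), int(s) + 8) for s in rng.integers(0, 50, 4)]
        preds = [((int(s), int(s) + 8), float(c))
                 for s, c in zip(rng.integers(0, 50, 6), rng.uniform(0.2, 0.9, 6))]
        scaled = [(obj, c * 0.5) for obj, c in preds]
        a1 = average_precision(preds, truths, _interval_iou, 0.5)
        a2 = average_precision(scaled, truths, _interval_iou, 0.5)
        assert a1 == pytest.approx(a2)

    def test_interpolation_rules_agree_on_dense_curves(self):
        rng = np.random.default_rng(21)
        truths = [(int(i * 12), int(i * 12) + 10) for i in range(120)]
        preds = []
        for i, t in enumerate(truths):
            jitter = int(rng.integers(0, 8)) if i % 3 == 0 else 0
            preds.append(((t[0] + jitter, t[1] + jitter), float(rng.random())))
        a_env = average_precision(preds, truths, _interval_iou, 0.5, "envelope")
        a_101 = average_precision(preds, truths, _interval_iou, 0.5, "101point")
        assert abs(a_env - a_101) <= 0.01


class TestMapRange:
    def test_single_class_mean_is_identity(self):
        assert mean_average_precision([0.94]) == pytest.approx(0.94)
        with pytest.raises(ValueError):
            mean_average_precision([])

    def test_identical_masks_score_one_everywhere(self):
        m = np.zeros((20, 20), bool)
        m[5:15, 5:15] = True
        assert map_range([(m, 0.9)], [m], mask_iou) == 1.0

    def test_constructed_iou_step_halves_the_range_mean(self):
        # Prediction is a 72-pixel subset of a 100-pixel truth: IoU 0.72
        # exactly, so AP=1 at thresholds <= 0.70 and 0 above -> mean 0.5.
        truth = np.zeros((10, 10), bool)
        truth[:, :] = True
        pred = np.zeros((10, 10), bool)
        pred.flat[:72] = True
        assert mask_iou(pred, truth) == pytest.approx(0.72)
        assert map_range([(pred, 0.9)], [truth], mask_iou) == pytest.approx(0.5)

    def test_nonincreasing_in_threshold(self):
        truth = np.zeros((10, 10), bool)
        truth[2:9, 2:9] = True
        pred = np.zeros((10, 10), bool)
        pred[3:9, 2:9] = True
        aps = [average_precision([(pred, 1.0)], [truth], mask_iou, t)
               for t in MAP_RANGE_THRESHOLDS]
        assert all(a >= b for a, b in zip(aps, aps[1:]))


class TestErrorMetrics:
    def test_single_pair_mape(self):
        em = error_metrics([0.2], [0.25])
        assert em.mape_percent == pytest.approx(20.0)

    def test_identical_vectors(self):
        em = error_metrics([0.1, 0.4], [0.1, 0.4])
        assert em.rmse == 0.0 and em.mape_percent == 0.0

    def test_hand_computed_triple(self):
        em = error_metrics([1, 2, 3], [2, 2, 2])
        assert em.rmse == pytest.approx(np.sqrt(2 / 3))
        assert em.mape_percent == pytest.approx(100 * (0.5 + 0 + 0.5) / 3)

    def test_zero_truths_excluded_with_count(self):
        em = error_metrics([0.1, 0.2], [0.0, 0.4])
        assert em.n_excluded_zero_truth == 1
        assert em.mape_percent == pytest.approx(50.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            error_metrics([1, 2], [1])
        with pytest.raises(ValueError):
            error_metrics([1.0], [0.0])
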