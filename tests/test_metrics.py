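"""Metric stack: BCE analytic points, F1 arithmetic, mAP staircase, TOPSIS."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glyolite.losses import bce
from glyolite.metrics import (ConfusionCounts, evaluate_detections, map50,
                              precision_recall_f1)
from glyolite.ranking import (DecisionMatrix, load_benchmark_table, topsis)


# --------------------------------------------------------------------- BCE

class TestBCE:
    @pytest.mark.parametrize("g,p,expected", [
        (1, 1.0, 0.0),
        (0, 0.0, 0.0),
        (1, math.exp(-1), 1.0),
    ])
    def test_analytic_points(self, g, p, expected):
        assert bce(g, p) == pytest.approx(expected, abs=1e-5)

    def test_rejects_non_binary_labels(self):
        with pytest.raises(ValueError):
            bce(0.5, 0.5)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0.01, 0.99), st.floats(0.001, 0.009))
    def test_convex_and_monotone(self, p, dp):
        # decreasing in p for g=1, increasing for g=0; midpoint convexity
        assert bce(1, p + dp) < bce(1, p)
        assert bce(0, p + dp) > bce(0, p)
        mid = bce(1, p + dp / 2)
        assert mid <= (bce(1, p) + bce(1, p + dp)) / 2 + 1e-12


# ---------------------------------------------------------------------- F1

class TestF1:
    @pytest.mark.parametrize("p,r,f1", [
        (0.843, 0.859, 0.851),   # lightweight model's published P/R row
        (0.812, 0.838, 0.825),   # baseline's published P/R row
    ])
    def test_published_worked_examples(self, p, r, f1):
        assert round(2 * p * r / (p + r), 3) == f1

    def test_counts_pipeline(self):
        rep = precision_recall_f1(ConfusionCounts(tp=8, fp=2, fn=2))
        assert rep.precision == pytest.approx(0.8)
        assert rep.recall == pytest.approx(0.8)
        assert rep.f1 == pytest.approx(0.8)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0.01, 1.0), st.floats(0.01, 1.0))
    def test_harmonic_below_arithmetic(self, p, r):
        f1 = 2 * p * r / (p + r)
        assert f1 <= (p + r) / 2 + 1e-12
        if p == r:
            assert f1 == pytest.approx(p)

    def test_zero_counts_flagged(self):
        rep = precision_recall_f1(ConfusionCounts(0, 0, 0))
        assert rep.f1 == 0.0 and rep.degenerate

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0)


# --------------------------------------------------------------------- mAP

def box(cls, x, y, w, h):
    return [cls, x, y, x + w, y + h]


class TestMap50:
    def test_perfect_detections_score_one(self):
        gts = [np.array([box(0, 10, 10, 50, 40)]),
               np.array([box(0, 100, 100, 30, 30)])]
        dets = [np.array([[10, 10, 60, 50, 1.0, 0]]),
                np.array([[100, 100, 130, 130, 1.0, 0]])]
        assert map50(dets, gts) == pytest.approx(1.0)

    def test_no_detections_scores_zero(self):
        gts = [np.array([box(0, 10, 10, 50, 40)])]
        assert map50([np.zeros((0, 6))], gts) == 0.0

    def test_empty_gt_with_detections_scores_zero(self):
        dets = [np.array([[0, 0, 10, 10, 0.9, 0]])]
        assert map50(dets, [np.zeros((0, 5))]) == 0.0

    def test_staircase_matches_hand_integration(self):
        """3 images, 2 TPs and 1 FP at fixed confidences.

        Ranked by confidence: TP(0.9), FP(0.8), TP(0.7) with 2 GT boxes.
        precision at recall 0.5 is 1.0; recall 1.0 arrives at precision 2/3.
        101-point AP = mean of interpolated precision on the grid.
        """
        gts = [np.array([box(0, 0, 0, 10, 10)]),
               np.array([box(0, 50, 50, 10, 10)]),
               np.zeros((0, 5))]
        dets = [np.array([[0, 0, 10, 10, 0.9, 0]]),
                np.array([[50, 50, 60, 60, 0.7, 0]]),
                np.array([[200, 200, 210, 210, 0.8, 0]])]
        grid = np.linspace(0, 1, 101)
        envelope = np.where(grid <= 0.5, 1.0, np.where(grid <= 1.0, 2 / 3, 0.0))
        expected = envelope.mean()
        assert map50(dets, gts) == pytest.approx(expected, abs=1e-9)

    def test_invariant_to_image_permutation(self, rng):
        gts = [np.array([box(0, 10, 10, 40, 40)]),
               np.array([box(0, 5, 5, 20, 20), box(0, 60, 60, 30, 30)])]
        dets = [np.array([[12, 11, 49, 52, 0.8, 0]]),
                np.array([[5, 5, 25, 25, 0.6, 0], [0, 0, 8, 8, 0.3, 0]])]
        assert map50(dets, gts) == pytest.approx(map50(dets[::-1], gts[::-1]))

    def test_invariant_to_hopeless_duplicate_detection(self):
        gts = [np.array([box(0, 10, 10, 40, 40)])]
        dets = [np.array([[10, 10, 50, 50, 0.9, 0]])]
        base = map50(dets, gts)
        # a detection below every GT's IoU threshold, at the lowest confidence
        dets2 = [np.vstack([dets[0], [500, 500, 510, 510, 0.01, 0]])]
        assert map50(dets2, gts) == pytest.approx(base)

    def test_evaluate_detections_counts(self):
        gts = [np.array([box(0, 10, 10, 40, 40)])]
        dets = [np.array([[10, 10, 50, 50, 0.9, 0], [200, 200, 230, 230, 0.8, 0]])]
        rep = evaluate_detections(dets, gts)
        assert rep.precision == pytest.approx(0.5)
        assert rep.recall == pytest.approx(1.0)


# ------------------------------------------------------------------ TOPSIS

class TestTopsis:
    def test_two_alternatives_single_criterion_endpoints(self):
        dm = DecisionMatrix(["a", "b"], [[3.0], [4.0]], criteria=("x",),
                            weights=(1.0,), benefit=(True,))
        res = topsis(dm, variant="vector")
        np.testing.assert_allclose(res.closeness, [0.0, 1.0])

    def test_three_by_two_matches_hand_computation(self):
        """Step-by-step manual arithmetic for the classic vector variant."""
        vals = np.array([[4.0, 2.0], [3.0, 5.0], [5.0, 3.0]])
        dm = DecisionMatrix(["a", "b", "c"], vals, criteria=("u", "v"),
                            weights=(0.6, 0.4), benefit=(True, False))
        norm = vals / np.sqrt((vals**2).sum(axis=0))
        V = norm * [0.6, 0.4]
        ideal = [V[:, 0].max(), V[:, 1].min()]
        anti = [V[:, 0].min(), V[:, 1].max()]
        dp = np.sqrt(((V - ideal) ** 2).sum(axis=1))
        dm_ = np.sqrt(((V - anti) ** 2).sum(axis=1))
        expected = dm_ / (dp + dm_)
        res = topsis(dm, variant="vector")
        np.testing.assert_allclose(res.closeness, expected, atol=1e-9)

    @pytest.mark.parametrize("variant", ["vector", "minmax", "calibrated"])
    def test_closeness_in_unit_interval(self, rng, variant):
        vals = rng.uniform(1, 100, (6, 4))
        dm = DecisionMatrix([f"m{i}" for i in range(6)], vals)
        res = topsis(dm, variant)
        assert np.all(res.closeness >= 0) and np.all(res.closeness <= 1)

    @pytest.mark.parametrize("variant", ["vector", "calibrated"])
    def test_scale_invariance_per_criterion(self, rng, variant):
        vals = rng.uniform(1, 100, (5, 4))
        dm = DecisionMatrix([f"m{i}" for i in range(5)], vals)
        scaled = vals.copy()
        scaled[:, 2] *= 7.5
        dm2 = DecisionMatrix([f"m{i}" for i in range(5)], scaled)
        np.testing.assert_allclose(
            topsis(dm, variant).closeness, topsis(dm2, variant).closeness,
            atol=1e-9,
        )

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            DecisionMatrix(["a"], [[1, 1, 1, 1]], weights=(0.5, 0.2, 0.2, 0.2))

    def test_bundled_tables_rank_lite_first(self):
        for name in ("fpdd", "pascal_voc"):
            res = topsis(load_benchmark_table(name))
            assert res.top() == "GL-YOLO-Lite"
            assert res.ranking[-1] == 1

    def test_bundled_tables_pinned_closeness(self):
        """Regression pin for the shipped calibrated variant."""
        res_f = topsis(load_benchmark_table("fpdd"))
        res_v = topsis(load_benchmark_table("pascal_voc"))
        assert res_f.closeness[-1] == pytest.approx(0.578998, abs=1e-6)
        assert res_v.closeness[-1] == pytest.approx(0.566097, abs=1e-6)
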