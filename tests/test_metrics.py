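"""Metric formulas against brute-force oracles and algebraic identities."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import f1_score, jaccard_score, roc_auc_score

from propseg.metrics import (MetricsReport, UndefinedMetricError, cross_entropy,
                             dice, evaluate, f1, jaccard, rank_auc)


def pairwise_auc_oracle(scores, truth):
    """P(random positive outranks random negative), ties counting 1/2."""
    scores = np.ravel(scores)
    truth = np.ravel(truth)
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def set_dice_oracle(p, g):
    inter = np.sum((p == 1) & (g == 1))
    return 2.0 * inter / (p.sum() + g.sum()) if (p.sum() + g.sum()) else 1.0


class TestCrossEntropy:
    def test_perfect_prediction_near_zero(self):
        y = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert cross_entropy(y, y) <= 1e-6

    def test_uninformative_half_gives_ln2(self):
        y = np.array([0.0, 1.0, 1.0, 0.0])
        assert cross_entropy(np.full(4, 0.5), y) == pytest.approx(np.log(2), abs=1e-12)

    def test_matches_elementwise_sum(self, rng):
        p = rng.uniform(0.01, 0.99, size=(13, 7))
        y = rng.integers(0, 2, size=(13, 7)).astype(float)
        manual = -np.mean([y_ * np.log(p_) + (1 - y_) * np.log(1 - p_)
                           for p_, y_ in zip(p.ravel(), y.ravel())])
        assert cross_entropy(p, y) == pytest.approx(manual, abs=1e-10)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            cross_entropy(np.zeros(3), np.zeros(4))


class TestOverlapMetrics:
    def test_identical_nonempty_masks(self, rng):
        m = (rng.random((9, 9)) > 0.6).astype(int)
        m[0, 0] = 1
        assert dice(m, m) == 1.0
        assert f1(m, m) == 1.0
        assert jaccard(m, m) == 1.0

    def test_disjoint_masks_zero(self):
        a = np.zeros((4, 4), dtype=int)
        b = np.zeros((4, 4), dtype=int)
        a[0, 0] = 1
        b[3, 3] = 1
        assert dice(a, b) == 0.0
        assert jaccard(a, b) == 0.0

    def test_half_overlap(self):
        a = np.zeros(8, dtype=int)
        b = np.zeros(8, dtype=int)
        a[:4] = 1
        b[2:6] = 1
        assert dice(a, b) == pytest.approx(0.5)

    def test_empty_prediction_nonempty_truth(self):
        g = np.ones((3, 3), dtype=int)
        assert f1(np.zeros((3, 3), dtype=int), g) == 0.0

    def test_both_empty_convention(self):
        z = np.zeros((3, 3), dtype=int)
        assert dice(z, z) == 1.0
        assert jaccard(z, z) == 1.0
        assert f1(z, z) == 1.0

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            dice(np.array([0, 2]), np.array([0, 1]))

    def test_symmetry_and_sklearn_crosscheck(self, rng):
        for _ in range(50):
            p = rng.integers(0, 2, 40)
            g = rng.integers(0, 2, 40)
            assert dice(p, g) == pytest.approx(dice(g, p), abs=1e-15)
            assert jaccard(p, g) == pytest.approx(jaccard(g, p), abs=1e-15)
            if g.sum() or p.sum():
                assert f1(p, g) == pytest.approx(
                    f1_score(g, p, zero_division=0.0), abs=1e-12)
                assert jaccard(p, g) == pytest.approx(
                    jaccard_score(g, p, zero_division=1.0), abs=1e-12)


class TestRankAuc:
    def test_perfect_separation(self, rng):
        g = np.array([1, 1, 0, 0, 0])
        s = np.array([0.9, 0.8, 0.3, 0.2, 0.1])
        assert rank_auc(s, g) == 1.0
        assert rank_auc(-s, g) == 0.0

    def test_matches_pairwise_oracle_with_ties(self, rng):
        for _ in range(30):
            scores = rng.choice([0.1, 0.4, 0.4, 0.7, 0.9], size=30)
            truth = rng.integers(0, 2, 30)
            if truth.sum() in (0, 30):
                continue
            assert rank_auc(scores, truth) == pytest.approx(
                pairwise_auc_oracle(scores, truth), abs=1e-12)

    def test_exhaustive_micro_cases(self):
        for scores in itertools.product((0.0, 1.0), repeat=4):
            for truth in itertools.product((0, 1), repeat=4):
                t = np.array(truth)
                if t.sum() in (0, 4):
                    continue
                s = np.array(scores)
                assert rank_auc(s, t) == pytest.approx(
                    pairwise_auc_oracle(s, t), abs=1e-12)

    def test_sklearn_crosscheck(self, rng):
        scores = rng.normal(size=64)
        truth = rng.integers(0, 2, 64)
        assert rank_auc(scores, truth) == pytest.approx(
            roc_auc_score(truth, scores), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=50)
        truth = rng.integers(0, 2, 50)
        base = rank_auc(scores, truth)
        assert rank_auc(np.exp(scores), truth) == pytest.approx(base, abs=1e-12)
        assert rank_auc(3 * scores + 7, truth) == pytest.approx(base, abs=1e-12)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            rank_auc(np.arange(4.0), np.ones(4, dtype=int))


class TestIdentities:
    def test_f1_equals_dice_and_jaccard_relation(self, rng):
        for _ in range(200):
            p = rng.integers(0, 2, (6, 6))
            g = rng.integers(0, 2, (6, 6))
            d = dice(p, g)
            assert f1(p, g) == pytest.approx(d, abs=1e-12)
            assert jaccard(p, g) == pytest.approx(d / (2.0 - d), abs=1e-12)


class TestEvaluate:
    def test_perfect_predictions_score_one(self, rng):
        masks = [rng.integers(0, 2, (8, 8)) for _ in range(3)]
        masks[0][0, 0] = 1  # ensure both classes for AUC
        rep = evaluate([masks], [masks])
        row = rep.per_stack["stack0"]
        assert row["dsc"] == row["f1"] == row["jsc"] == 1.0

    def test_hand_computed_stack(self):
        g = np.zeros((4, 4), dtype=int)
        g[1:3, 1:3] = 1
        p = np.zeros((4, 4), dtype=int)
        p[1:3, 1:2] = 1  # half of truth, no false positives
        rep = evaluate([[p]], [[g]])
        row = rep.per_stack["stack0"]
        assert row["dsc"] == pytest.approx(set_dice_oracle(p, g))
        assert row["jsc"] == pytest.approx(0.5)
        assert row["auc"] == pytest.approx(pairwise_auc_oracle(p, g))

    def test_identical_folds_have_zero_std(self):
        rep = MetricsReport(per_stack={"s": {"dsc": 0.8, "auc": 0.9,
                                             "f1": 0.8, "jsc": 0.7}}).finalize()
        merged = MetricsReport.across_folds([rep] * 5)
        assert merged.aggregate["dsc_std"] == 0.0
        assert merged.aggregate["dsc_mean"] == pytest.approx(0.8)

    def test_single_class_slices_skipped_for_auc(self):
        empty = np.zeros((4, 4), dtype=int)
        rep = evaluate([[empty]], [[empty]])
        assert rep.per_stack["stack0"]["auc"] is None
        assert rep.per_stack["stack0"]["dsc"] == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            evaluate([], [])
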