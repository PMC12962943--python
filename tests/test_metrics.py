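"""AUC, Youden threshold, confusion metrics, slope, decision curves, folds.

AUC and the Youden threshold are checked against brute-force oracles
(pair counting; exhaustive midpoint search) on random instances.
"""

from __future__ import annotations

import numpy as np
import pytest

from msirad.metrics import (
    DesignError,
    confusion_metrics,
    decision_curve,
    discrimination_slope,
    roc_auc,
    stratified_folds,
    youden_threshold,
)


def brute_force_auc(scores, y):
    """Oracle: count concordant positive-negative pairs (ties half)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_youden(scores, y):
    """Oracle: exhaustive search over midpoints of adjacent distinct scores."""
    distinct = np.unique(scores)
    if distinct.size == 1:
        return float(distinct[0])
    best = None
    for t in (distinct[:-1] + distinct[1:]) / 2:
        pred = scores >= t
        sens = pred[y == 1].mean()
        spec = (~pred[y == 0]).mean()
        key = (sens + spec - 1, spec, t)
        if best is None or key > best[0]:
            best = (key, t)
    return best[1]


class TestAuc:
    def test_perfect_ranking(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert roc_auc([0.5] * 6, [1, 1, 0, 0, 0, 0]) == 0.5

    def test_pair_counting_example(self):
        y = np.array([1, 1, 0, 0, 0])
        assert roc_auc([0.9, 0.8, 0.7, 0.3, 0.2], y) == 1.0
        assert roc_auc([0.9, 0.5, 0.7, 0.3, 0.2], y) == pytest.approx(5 / 6)

    def test_single_class_rejected(self):
        with pytest.raises(DesignError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            n = rng.integers(4, 30)
            y = np.zeros(n, int)
            y[: rng.integers(1, n)] = 1
            rng.shuffle(y)
            if y.sum() in (0, n):
                continue
            scores = np.round(rng.uniform(size=n), 2)  # coarse grid: forces ties
            assert roc_auc(scores, y) == pytest.approx(brute_force_auc(scores, y))


class TestYouden:
    def test_oracle_computed_reference_instance(self):
        # pos {0.8, 0.9} vs neg {0.1, 0.2, 0.7}: midpoint 0.75 separates
        # the classes perfectly (0.7 < 0.75 is a true negative), so J = 1.
        scores = np.array([0.8, 0.9, 0.1, 0.2, 0.7])
        y = np.array([1, 1, 0, 0, 0])
        t = youden_threshold(scores, y)
        assert t == pytest.approx(0.75)
        cm = confusion_metrics(scores, y, t)
        assert cm["sensitivity"] == 1.0 and cm["specificity"] == 1.0

    def test_separated_scores_reach_j_one(self):
        scores = np.array([0.9, 0.8, 0.3, 0.2])
        y = np.array([1, 1, 0, 0])
        t = youden_threshold(scores, y)
        cm = confusion_metrics(scores, y, t)
        assert cm["sensitivity"] + cm["specificity"] - 1 == pytest.approx(1.0)
        assert 0.3 < t <= 0.8

    def test_degenerate_equal_scores(self):
        scores = np.full(5, 0.4)
        y = np.array([1, 0, 0, 1, 0])
        t = youden_threshold(scores, y)
        cm = confusion_metrics(scores, y, t)
        assert cm["sensitivity"] + cm["specificity"] - 1 == pytest.approx(0.0)

    def test_matches_exhaustive_midpoint_search(self, rng):
        for _ in range(100):
            n = rng.integers(5, 25)
            y = np.zeros(n, int)
            y[: rng.integers(1, n)] = 1
            rng.shuffle(y)
            if y.sum() in (0, n):
                continue
            scores = np.round(rng.uniform(size=n), 1)
            assert youden_threshold(scores, y) == pytest.approx(
                brute_force_youden(scores, y)
            )


class TestConfusion:
    def test_threshold_below_all_scores(self):
        y = np.array([1, 0, 0, 0, 1])
        cm = confusion_metrics(np.array([0.5, 0.6, 0.7, 0.8, 0.9]), y, 0.0)
        assert cm["sensitivity"] == 1.0 and cm["specificity"] == 0.0
        assert cm["ppv"] == pytest.approx(0.4)  # prevalence

    def test_threshold_above_all_scores(self):
        y = np.array([1, 0, 0, 0, 1])
        cm = confusion_metrics(np.array([0.1] * 5), y, 0.99)
        assert cm["specificity"] == 1.0 and cm["sensitivity"] == 0.0
        assert cm["npv"] == pytest.approx(0.6)  # 1 - prevalence

    def test_undefined_ppv_reported_missing(self):
        y = np.array([1, 1, 0, 0])
        cm = confusion_metrics(np.array([0.1, 0.1, 0.1, 0.1]), y, 0.5)
        assert np.isnan(cm["ppv"])  # nobody predicted positive
        assert cm["npv"] == pytest.approx(0.5)


class TestSlope:
    def test_direct_arithmetic(self):
        y = np.array([1, 1, 0, 0])
        assert discrimination_slope([0.7, 0.7, 0.3, 0.3], y) == pytest.approx(0.4)

    def test_identical_distributions_give_zero(self):
        y = np.array([1, 1, 0, 0])
        assert discrimination_slope([0.5, 0.3, 0.5, 0.3], y) == pytest.approx(0.0)

    def test_extreme_case(self):
        y = np.array([1, 1, 0, 0, 0])
        assert discrimination_slope([1, 1, 0, 0, 0], y) == 1.0


class TestDecisionCurve:
    def test_treat_none_is_zero_everywhere(self, rng):
        y = np.r_[np.ones(5, int), np.zeros(20, int)]
        dc = decision_curve(rng.uniform(size=25), y)
        assert (dc.treat_none == 0).all()

    def test_treat_all_closed_form(self):
        y = np.r_[np.ones(4, int), np.zeros(16, int)]  # prevalence 0.2
        dc = decision_curve(np.full(20, 0.5), y, thresholds=[0.1])
        assert dc.treat_all[0] == pytest.approx(0.2 - 0.8 / 9)

    def test_perfect_model_attains_prevalence(self):
        y = np.r_[np.ones(4, int), np.zeros(16, int)]
        scores = 0.9 * y + 0.05
        dc = decision_curve(scores, y, thresholds=np.arange(0.1, 0.9, 0.1))
        np.testing.assert_allclose(dc.net_benefit, 0.2)

    def test_boundary_thresholds_rejected(self):
        y = np.array([1, 0, 1, 0])
        with pytest.raises(ValueError):
            decision_curve([0.1, 0.2, 0.3, 0.4], y, thresholds=[0.5, 1.0])


class TestStratifiedFolds:
    def test_study_design_fold_sizes(self):
        y = np.r_[np.ones(19, int), np.zeros(76, int)]
        folds = stratified_folds(y, k=3, seed=5)
        pos_sizes = sorted(np.bincount(folds[y == 1]))
        neg_sizes = sorted(np.bincount(folds[y == 0]))
        assert pos_sizes == [6, 6, 7]
        assert neg_sizes == [25, 25, 26]

    def test_partition_contract(self, rng):
        y = rng.integers(0, 2, size=40)
        y[:4] = 1
        y[-4:] = 0
        folds = stratified_folds(y, k=3, seed=1)
        assert set(folds) == {0, 1, 2}
        assert (folds >= 0).all()

    def test_two_seeds_differ_with_same_profile(self):
        y = np.r_[np.ones(19, int), np.zeros(76, int)]
        f1 = stratified_folds(y, 3, seed=1)
        f2 = stratified_folds(y, 3, seed=2)
        assert not np.array_equal(f1, f2)
        assert sorted(np.bincount(f1)) == sorted(np.bincount(f2))

    def test_small_class_is_design_error(self):
        with pytest.raises(DesignError):
            stratified_folds(np.array([1, 1, 0, 0, 0, 0]), k=3, seed=0)
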