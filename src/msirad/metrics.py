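"""Discrimination metrics and cross-validation fold construction.

All metrics operate on a vector of risk scores in [0, 1] and a binary label
vector (1 = MSI-H). Dichotomization is boundary-inclusive: a case is
predicted positive when its score is >= the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


class DesignError(ValueError):
    """A fold/metric request the class sizes cannot support."""


def _check_two_classes(y: np.ndarray) -> None:
    if not ((y == 1).any() and (y == 0).any()):
        raise DesignError("both classes must be present")


def roc_auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    _check_two_classes(y)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    ranks = rankdata(scores)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def _sens_spec(scores, y, threshold):
    pred = scores >= threshold
    sens = float(pred[y == 1].mean())
    spec = float((~pred[y == 0]).mean())
    return sens, spec


def youden_threshold(scores, labels) -> float:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Candidates are the midpoints between adjacent distinct scores; ties on J
    are broken toward higher specificity (then the higher threshold). With a
    single distinct score the degenerate midpoint is that score itself.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    _check_two_classes(y)
    distinct = np.unique(scores)
    if distinct.size == 1:
        return float(distinct[0])
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    best = None
    for t in candidates:
        sens, spec = _sens_spec(scores, y, t)
        key = (sens + spec - 1.0, spec, t)
        if best is None or key > best[0]:
            best = (key, t)
    return float(best[1])


def confusion_metrics(scores, labels, threshold) -> dict[str, float]:
    """Sensitivity, specificity, PPV, NPV at a threshold (score >= t positive).

    A zero-denominator predictive value is reported as NaN (missing), not 0.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    _check_two_classes(y)
    pred = scores >= threshold
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    return {
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "ppv": tp / (tp + fp) if (tp + fp) > 0 else float("nan"),
        "npv": tn / (tn + fn) if (tn + fn) > 0 else float("nan"),
    }


def discrimination_slope(scores, labels) -> float:
    """Mean predicted score of positives minus mean predicted score of negatives."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    _check_two_classes(y)
    return float(scores[y == 1].mean() - scores[y == 0].mean())


@dataclass
class DecisionCurve:
    """Net benefit across threshold probabilities, with reference strategies."""

    thresholds: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray


DEFAULT_DCA_GRID = np.round(np.arange(0.01, 1.0, 0.01), 2)


def decision_curve(scores, labels, thresholds=DEFAULT_DCA_GRID) -> DecisionCurve:
    """Decision-curve analysis: NB(t) = TP/n - FP/n * t/(1-t)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    _check_two_classes(y)
    thresholds = np.asarray(thresholds, dtype=float)
    if ((thresholds <= 0) | (thresholds >= 1)).any():
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = y.size
    prevalence = y.mean()
    nb = np.empty_like(thresholds)
    for i, t in enumerate(thresholds):
        pred = scores >= t
        tp = (pred & (y == 1)).sum() / n
        fp = (pred & (y == 0)).sum() / n
        nb[i] = tp - fp * t / (1.0 - t)
    treat_all = prevalence - (1.0 - prevalence) * thresholds / (1.0 - thresholds)
    return DecisionCurve(
        thresholds=thresholds,
        net_benefit=nb,
        treat_all=treat_all,
        treat_none=np.zeros_like(thresholds),
    )


def stratified_folds(labels, k: int = 3, seed: int | np.random.SeedSequence = 0) -> np.ndarray:
    """Stratified fold assignment: class-wise shuffled round-robin.

    Per-class fold sizes differ by at most one; deterministic given seed.
    """
    y = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    folds = np.full(y.size, -1, dtype=int)
    for cls in (1, 0):
        idx = np.flatnonzero(y == cls)
        if idx.size < k:
            raise DesignError(f"class {cls} has {idx.size} members, fewer than k={k}")
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % k
    return folds
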