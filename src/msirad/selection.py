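"""Univariate screening and in-fold feature selection.

Screening is descriptive: every feature is tested against MSI status with a
two-sided Wilcoxon rank-sum test at alpha = 0.05, uncorrected (the per-region
significant counts are reported, but screening does not gate the modeling
path). In-fold selection is minimum-redundancy maximum-relevance (mRMR,
greedy MID scheme over plug-in mutual information) followed by forward
selection driven by inner 3-fold cross-validated AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu

from . import modeling
from .metrics import DesignError, roc_auc, stratified_folds

logger = logging.getLogger(__name__)

ALPHA = 0.05
MI_BINS = 4
FORWARD_CAP = 10
FORWARD_IMPROVEMENT = 1e-3


@dataclass
class ScreenResult:
    """Per-feature two-sided p-values and the alpha = 0.05 significance flags."""

    feature_names: list[str]
    p_values: np.ndarray
    alpha: float = ALPHA

    @property
    def significant(self) -> np.ndarray:
        return self.p_values < self.alpha

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())


@dataclass
class SelectionRecord:
    """One fold's mRMR ranking and the forward-selected subset."""

    fold_id: tuple[int, int]  # (repetition, fold)
    ranked: list[str]
    selected: list[str]
    scores: dict = field(default_factory=dict)


def wilcoxon_feature_pvalue(x, y) -> float:
    """Two-sided rank-sum p-value for one feature.

    Exact null distribution when both groups have <= 10 members and the
    feature is tie-free; tie-corrected normal approximation otherwise. A
    constant feature is uninformative and gets p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y).astype(int)
    a = x[y == 1]
    b = x[y == 0]
    if a.size == 0 or b.size == 0:
        raise DesignError("both classes must be nonempty")
    if np.unique(x).size == 1:
        logger.debug("constant feature: p = 1 by convention")
        return 1.0
    exact = a.size <= 10 and b.size <= 10 and np.unique(x).size == x.size
    res = mannwhitneyu(
        a,
        b,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=False,
    )
    return float(min(res.pvalue, 1.0))


def wilcoxon_screen(values: np.ndarray, labels, feature_names=None, alpha=ALPHA) -> ScreenResult:
    """Screen every feature column of a (cases x features) matrix."""
    values = np.asarray(values, dtype=float)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(values.shape[1])]
    p = np.array(
        [wilcoxon_feature_pvalue(values[:, j], labels) for j in range(values.shape[1])]
    )
    return ScreenResult(feature_names=list(feature_names), p_values=p, alpha=alpha)


def _equal_frequency_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Discretize by quantile edges; rank-invariant under monotone transforms."""
    edges = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="left")


def mutual_information(x, y, bins: int = MI_BINS) -> float:
    """Plug-in mutual information (bits) after equal-frequency binning.

    ``x`` is always discretized; ``y`` is used as-is when already discrete
    (<= ``bins`` distinct values, e.g. the binary MSI label) and discretized
    the same way otherwise (feature-feature redundancy terms).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    xb = _equal_frequency_bins(x, bins)
    if np.unique(xb).size < 2:
        return 0.0
    yb = y if np.unique(y).size <= bins else _equal_frequency_bins(y, bins)
    xi = np.unique(xb, return_inverse=True)[1]
    yi = np.unique(yb, return_inverse=True)[1]
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    pos = joint > 0
    mi = (joint[pos] * np.log2(joint[pos] / (px @ py)[pos])).sum()
    return float(max(mi, 0.0))


def mrmr_rank(values: np.ndarray, labels, k: int, feature_names=None, bins: int = MI_BINS) -> list[int]:
    """Greedy mRMR ranking under the MID (difference) scheme.

    First pick maximizes relevance MI(f, y); each subsequent pick maximizes
    MI(f, y) minus the mean MI with the already-selected features. Ties break
    toward the earlier registry (column) index. Returns column indices.
    """
    values = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(int)
    n_features = values.shape[1]
    if k <= 0:
        raise ValueError("k must be positive")
    k = min(k, n_features)

    relevance = np.array(
        [mutual_information(values[:, j], y, bins) for j in range(n_features)]
    )
    selected: list[int] = []
    remaining = list(range(n_features))
    red_sum = np.zeros(n_features)
    while len(selected) < k:
        if selected:
            objective = relevance - red_sum / len(selected)
        else:
            objective = relevance.copy()
        obj = objective[remaining]
        pick = remaining[int(np.argmax(obj))]  # argmax takes the first max: registry order
        selected.append(pick)
        remaining.remove(pick)
        for j in remaining:
            red_sum[j] += mutual_information(values[:, j], values[:, pick], bins)
    return selected


def _inner_cv_auc(values, y, cols, kind, seed, model_config) -> float:
    """Pooled out-of-fold AUC of an inner stratified 3-fold on training data."""
    for attempt in range(5):
        try:
            folds = stratified_folds(y, k=3, seed=np.random.SeedSequence([seed, attempt]))
            oof = np.empty(y.size)
            for f in range(3):
                tr = folds != f
                model = modeling.train_risk_model(
                    kind, values[np.ix_(tr, cols)], y[tr], seed=seed, config=model_config
                )
                oof[~tr] = modeling.score(model, values[np.ix_(~tr, cols)])
            return roc_auc(oof, y)
        except (DesignError, modeling.TrainingError):
            logger.warning("degenerate inner fold; repartitioning (attempt %d)", attempt + 1)
    raise DesignError("inner folds degenerate after 5 repartitions")


def forward_select(
    ranked: list[int],
    values: np.ndarray,
    labels,
    classifier_kind: str,
    cap: int = FORWARD_CAP,
    seed: int = 0,
    improvement: float = FORWARD_IMPROVEMENT,
    model_config: modeling.ModelConfig = modeling.ModelConfig(),
) -> tuple[list[int], dict]:
    """Walk the mRMR order, keeping features that improve inner 3-fold AUC.

    The first candidate is always kept (the subset is never empty); each later
    candidate is kept only if it raises the inner cross-validated AUC by more
    than ``improvement``. Stops at ``cap`` features or the end of the list.
    Returns (selected column indices, diagnostics).
    """
    if not ranked:
        raise ValueError("ranked candidate list is empty")
    values = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(int)

    selected = [ranked[0]]
    best = _inner_cv_auc(values, y, selected, classifier_kind, seed, model_config)
    trace = [(ranked[0], best, True)]
    for cand in ranked[1:]:
        if len(selected) >= cap:
            break
        auc = _inner_cv_auc(values, y, selected + [cand], classifier_kind, seed, model_config)
        keep = auc > best + improvement
        trace.append((cand, auc, keep))
        if keep:
            selected.append(cand)
            best = auc
    return selected, {"inner_auc": best, "trace": trace}
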