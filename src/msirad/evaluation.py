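"""Repeated stratified 3-fold cross-validation of the three radiomic models.

Per repetition and fold, feature selection (mRMR + forward selection) and
classifier training happen on the training fold only; an inner stratified
3-fold on the training cases produces leak-free out-of-fold tumor/pancreas
channel scores on which the logistic fusion combiner is trained; the region
models are then refit on the full training fold and applied to the test fold,
and the fused test score is the combiner applied to the two test-fold channel
scores. Per-repetition metrics (AUC, Youden-thresholded confusion metrics,
discrimination slope) are computed on the pooled out-of-fold scores, and the
report carries their means with 95% percentile intervals across repetitions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import modeling
from .cohort_io import FeatureTable
from .metrics import (
    DesignError,
    confusion_metrics,
    decision_curve,
    discrimination_slope,
    roc_auc,
    stratified_folds,
    youden_threshold,
)
from .selection import SelectionRecord, forward_select, mrmr_rank, wilcoxon_screen

# Re-exported metric surface; this module is the pipeline's evaluation API.
__all__ = [
    "CVConfig",
    "CVResult",
    "PerformanceReport",
    "run_repeated_cv",
    "fit_score_fold",
    "selection_frequency",
    "summarize",
    "roc_auc",
    "youden_threshold",
    "confusion_metrics",
    "discrimination_slope",
    "decision_curve",
    "stratified_folds",
    "MODELS",
]

logger = logging.getLogger(__name__)

MODELS = ("TumRad", "PancRad", "IntRad")
METRIC_NAMES = ("auc", "sensitivity", "specificity", "ppv", "npv", "slope", "threshold")


@dataclass(frozen=True)
class CVConfig:
    """Settings of the repeated stratified cross-validation."""

    n_repetitions: int = 100
    k: int = 3
    classifier: str = "logistic_regression"
    mrmr_k: int = 15
    forward_cap: int = 10
    forward_improvement: float = 1e-3
    # restrict in-fold selection to features passing the training-fold
    # Wilcoxon screen (off by default: screening is descriptive)
    screen_as_prefilter: bool = False
    seed: int = 0
    model_config: modeling.ModelConfig = modeling.ModelConfig()


@dataclass
class CVResult:
    """Out-of-fold scores, per-fold selection records and per-repetition metrics."""

    classifier: str
    case_ids: list[str]
    labels: np.ndarray
    oof_scores: dict  # model -> (n_repetitions, n_cases)
    selections: dict  # region -> list[SelectionRecord]
    per_repetition: pd.DataFrame
    config: CVConfig
    fold_assignments: np.ndarray | None = None  # (n_repetitions, n_cases)


def _derived_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] & 0x7FFFFFFF)


def _inner_channel_scores(Xt, Xp, y, sel_t, sel_p, kind, seed, mcfg):
    """Out-of-fold tumor/pancreas scores from an inner 3-fold on training cases."""
    for attempt in range(5):
        try:
            folds = stratified_folds(y, k=3, seed=np.random.SeedSequence([seed, attempt]))
            oof_t = np.empty(y.size)
            oof_p = np.empty(y.size)
            for f in range(3):
                tr = folds != f
                mt = modeling.train_risk_model(
                    kind, Xt[np.ix_(tr, sel_t)], y[tr], seed=seed, config=mcfg
                )
                mp = modeling.train_risk_model(
                    kind, Xp[np.ix_(tr, sel_p)], y[tr], seed=seed, config=mcfg
                )
                oof_t[~tr] = modeling.score(mt, Xt[np.ix_(~tr, sel_t)])
                oof_p[~tr] = modeling.score(mp, Xp[np.ix_(~tr, sel_p)])
            return oof_t, oof_p
        except (DesignError, modeling.TrainingError):
            logger.warning("degenerate inner fusion fold; repartitioning (%d)", attempt + 1)
    raise DesignError("fusion inner folds degenerate after 5 repartitions")


def fit_score_fold(
    Xt_tr: np.ndarray,
    Xp_tr: np.ndarray,
    y_tr: np.ndarray,
    Xt_te: np.ndarray,
    Xp_te: np.ndarray,
    names_t: list[str],
    names_p: list[str],
    kind: str,
    fold_seed: int,
    config: CVConfig,
):
    """Fit one fold (selection, region models, fusion) and score the test fold.

    Test-fold labels are not an input: out-of-fold scores are a function of
    the training data and the test features only, which makes the
    cross-validation leak-free by construction.

    Returns ``(tum_scores, panc_scores, fused_scores, selection_records)``.
    """
    mcfg = config.model_config
    sel_cols = {}
    records = {}
    for region, Xtr, nms in (("tumor", Xt_tr, names_t), ("pancreas", Xp_tr, names_p)):
        pool = np.arange(Xtr.shape[1])
        if config.screen_as_prefilter:
            flags = wilcoxon_screen(Xtr, y_tr).significant
            if flags.any():
                pool = np.flatnonzero(flags)
        ranked = [int(pool[j]) for j in mrmr_rank(Xtr[:, pool], y_tr, k=config.mrmr_k)]
        cols, diag = forward_select(
            ranked,
            Xtr,
            y_tr,
            kind,
            cap=config.forward_cap,
            seed=fold_seed,
            improvement=config.forward_improvement,
            model_config=mcfg,
        )
        sel_cols[region] = cols
        records[region] = SelectionRecord(
            fold_id=(-1, -1),  # filled in by the caller
            ranked=[nms[j] for j in ranked],
            selected=[nms[j] for j in cols],
            scores={"inner_auc": diag["inner_auc"]},
        )

    oof_t, oof_p = _inner_channel_scores(
        Xt_tr, Xp_tr, y_tr, sel_cols["tumor"], sel_cols["pancreas"], kind, fold_seed, mcfg
    )
    fusion = modeling.train_fusion(oof_t, oof_p, y_tr)

    mt = modeling.train_risk_model(
        kind, Xt_tr[:, sel_cols["tumor"]], y_tr, seed=fold_seed, config=mcfg
    )
    mp = modeling.train_risk_model(
        kind, Xp_tr[:, sel_cols["pancreas"]], y_tr, seed=fold_seed, config=mcfg
    )
    s_t = modeling.score(mt, Xt_te[:, sel_cols["tumor"]])
    s_p = modeling.score(mp, Xp_te[:, sel_cols["pancreas"]])
    s_f = modeling.fuse(fusion, s_t, s_p)
    return s_t, s_p, s_f, records


def run_repeated_cv(
    tumor_table: FeatureTable,
    pancreas_table: FeatureTable,
    labels,
    config: CVConfig = CVConfig(),
) -> CVResult:
    """The full cross-validated pipeline for one classifier kind.

    Deterministic given ``config.seed``: every repetition/fold seed is derived
    from it.
    """
    if tumor_table.case_ids != pancreas_table.case_ids:
        raise ValueError("tumor and pancreas tables are not aligned on cases")
    y = np.asarray(labels).astype(int)
    n = y.size
    if n != len(tumor_table.case_ids):
        raise ValueError("labels are not aligned with the feature tables")
    Xt = tumor_table.values
    Xp = pancreas_table.values
    names_t = tumor_table.feature_names
    names_p = pancreas_table.feature_names
    kind = config.classifier

    oof = {m: np.empty((config.n_repetitions, n)) for m in MODELS}
    fold_assignments = np.empty((config.n_repetitions, n), dtype=int)
    selections: dict[str, list[SelectionRecord]] = {"tumor": [], "pancreas": []}
    rows = []

    for rep in range(config.n_repetitions):
        rep_done = False
        for attempt in range(5):
            try:
                folds = stratified_folds(
                    y, k=config.k, seed=np.random.SeedSequence([config.seed, rep, attempt])
                )
                rep_sel: dict[str, list[SelectionRecord]] = {"tumor": [], "pancreas": []}
                rep_oof = {m: np.empty(n) for m in MODELS}
                for f in range(config.k):
                    tr = folds != f
                    te = ~tr
                    fold_seed = _derived_seed(config.seed, rep, f)
                    s_t, s_p, s_f, records = fit_score_fold(
                        Xt[tr], Xp[tr], y[tr], Xt[te], Xp[te],
                        names_t, names_p, kind, fold_seed, config,
                    )
                    for region, rec in records.items():
                        rec.fold_id = (rep, f)
                        rep_sel[region].append(rec)
                    rep_oof["TumRad"][te] = s_t
                    rep_oof["PancRad"][te] = s_p
                    rep_oof["IntRad"][te] = s_f
                fold_assignments[rep] = folds
                rep_done = True
                break
            except (DesignError, modeling.TrainingError) as exc:
                logger.warning("repetition %d reseeded (%s)", rep, exc)
        if not rep_done:
            raise DesignError(f"repetition {rep} degenerate after 5 reseeds")

        for region in ("tumor", "pancreas"):
            selections[region].extend(rep_sel[region])
        for m in MODELS:
            scores = rep_oof[m]
            oof[m][rep] = scores
            thr = youden_threshold(scores, y)
            cm = confusion_metrics(scores, y, thr)
            rows.append(
                {
                    "repetition": rep,
                    "model": m,
                    "classifier": kind,
                    "auc": roc_auc(scores, y),
                    "threshold": thr,
                    "slope": discrimination_slope(scores, y),
                    **cm,
                }
            )

    return CVResult(
        classifier=kind,
        case_ids=list(tumor_table.case_ids),
        labels=y,
        oof_scores=oof,
        selections=selections,
        per_repetition=pd.DataFrame(rows),
        config=config,
        fold_assignments=fold_assignments,
    )


def selection_frequency(
    result: CVResult, threshold: float = 0.70, region: str = "tumor"
) -> tuple[pd.Series, list[str]]:
    """Fraction of (repetition x fold) fits selecting each feature, and the
    features above ``threshold`` (the >70% reporting rule)."""
    records = result.selections[region]
    if not records:
        return pd.Series(dtype=float), []
    counts: dict[str, int] = {}
    for rec in records:
        for name in rec.selected:
            counts[name] = counts.get(name, 0) + 1
    freq = pd.Series(counts, dtype=float).sort_values(ascending=False) / len(records)
    top = freq[freq > threshold].index.tolist()
    return freq, top


@dataclass
class PerformanceReport:
    """Mean per-repetition metrics with 95% percentile intervals, per model x classifier."""

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"metadata": self.metadata, "rows": self.table.to_dict(orient="records")},
            indent=2,
            default=float,
        )


def summarize(results: CVResult | list[CVResult]) -> PerformanceReport:
    """Aggregate one or more CV results into the model x classifier report."""
    if isinstance(results, CVResult):
        results = [results]
    frames = [r.per_repetition for r in results]
    if any(f["repetition"].nunique() < 2 for f in frames):
        raise ValueError("summarize needs at least 2 repetitions")
    per_rep = pd.concat(frames, ignore_index=True)

    rows = []
    for (model, clf), grp in per_rep.groupby(["model", "classifier"], sort=False):
        row = {"model": model, "classifier": clf}
        for metric in METRIC_NAMES:
            vals = grp[metric].to_numpy(dtype=float)
            row[metric] = float(np.nanmean(vals))
            row[f"{metric}_lo"] = float(np.nanpercentile(vals, 2.5))
            row[f"{metric}_hi"] = float(np.nanpercentile(vals, 97.5))
        rows.append(row)
    table = pd.DataFrame(rows)

    cfg = results[0].config
    metadata = {
        "n_repetitions": int(cfg.n_repetitions),
        "k": int(cfg.k),
        "interval": "2.5/97.5 percentiles across repetitions",
        "youden_policy": (
            "threshold refit per repetition on the pooled out-of-fold scores it "
            "evaluates; the resulting optimism is documented, not corrected"
        ),
        "classifiers": sorted({r.classifier for r in results}),
        "seed": int(cfg.seed),
    }
    return PerformanceReport(table=table, metadata=metadata)
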