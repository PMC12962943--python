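"""ROC and decision-curve figures for evaluation reports."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from sklearn.metrics import roc_curve

from .evaluation import MODELS, CVResult
from .metrics import decision_curve


def plot_roc(result: CVResult, path: str | Path, repetition: int = 0) -> None:
    """ROC curves of the three models from one repetition's pooled OOF scores."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for model in MODELS:
        scores = result.oof_scores[model][repetition]
        fpr, tpr, _ = roc_curve(result.labels, scores)
        mean_auc = result.per_repetition.query("model == @model")["auc"].mean()
        ax.plot(fpr, tpr, label=f"{model} (mean AUC {mean_auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"ROC ({result.classifier})")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_decision_curves(
    result: CVResult, path: str | Path, repetition: int = 0, band=(0.10, 0.70)
) -> None:
    """Net benefit of each model vs treat-all/treat-none, one repetition."""
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    dc = None
    for model in MODELS:
        dc = decision_curve(result.oof_scores[model][repetition], result.labels)
        ax.plot(dc.thresholds, dc.net_benefit, label=model)
    ax.plot(dc.thresholds, dc.treat_all, color="gray", ls="--", label="treat all")
    ax.plot(dc.thresholds, dc.treat_none, color="black", ls=":", label="treat none")
    ax.axvspan(*band, color="0.92", zorder=0)
    ax.set_ylim(bottom=max(-0.05, np.nanmin(dc.treat_all) - 0.02))
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.set_title(f"Decision curves ({result.classifier})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
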