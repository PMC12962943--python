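"""Classifier back-ends and tumor/pancreas probability-score fusion.

Four risk-model kinds are supported — logistic regression, RBF-kernel SVM,
random forest and XGBoost — each emitting a risk score in [0, 1]. The 1:4
class imbalance is handled by inverse-prevalence class weights for every
kind (resampling would disturb the stratified fold counts). Features are
standardized (training-fold mean/sd) for the two margin-based kinds; the SVM
obtains probabilities through Platt scaling on the training data.

The combined model fuses the tumor-model and pancreas-model probability
scores through a two-input logistic regression (plus intercept), trained on
leak-free out-of-fold channel scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

CLASSIFIER_KINDS = ("logistic_regression", "svm", "random_forest", "xgboost")


class TrainingError(ValueError):
    pass


class SchemaError(KeyError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Fixed hyperparameters (recorded in every report; no tuning is done)."""

    logistic_c: float = 1.0
    svm_c: float = 1.0
    rf_n_estimators: int = 500
    xgb_n_estimators: int = 200
    xgb_max_depth: int = 3
    xgb_learning_rate: float = 0.1


@dataclass
class RiskModel:
    """A fitted classifier bound to its selected feature names."""

    kind: str
    feature_names: list[str]
    estimator: object
    seed: int
    metadata: dict = field(default_factory=dict)


def _build_estimator(kind: str, y: np.ndarray, seed: int, cfg: ModelConfig):
    if kind == "logistic_regression":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "clf",
                    LogisticRegression(
                        C=cfg.logistic_c,
                        class_weight="balanced",
                        max_iter=2000,
                    ),
                ),
            ]
        )
    if kind == "svm":
        svc = SVC(
            C=cfg.svm_c,
            kernel="rbf",
            gamma="scale",
            class_weight="balanced",
            random_state=seed,
        )
        # Platt (sigmoid) scaling fitted on the training data via internal CV
        calibrated = CalibratedClassifierCV(svc, method="sigmoid", cv=3, ensemble=False)
        return Pipeline([("scale", StandardScaler()), ("clf", calibrated)])
    if kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=cfg.rf_n_estimators,
            max_features="sqrt",
            class_weight="balanced",
            random_state=seed,
            n_jobs=1,
        )
    if kind == "xgboost":
        n_pos = int((y == 1).sum())
        n_neg = int((y == 0).sum())
        return XGBClassifier(
            n_estimators=cfg.xgb_n_estimators,
            max_depth=cfg.xgb_max_depth,
            learning_rate=cfg.xgb_learning_rate,
            scale_pos_weight=n_neg / n_pos,
            random_state=seed,
            n_jobs=1,
            verbosity=0,
            eval_metric="logloss",
        )
    raise ValueError(f"unknown classifier kind {kind!r}")


def _as_matrix(X, feature_names: list[str]) -> np.ndarray:
    """Name-based column selection; order of the input columns is irrelevant."""
    if isinstance(X, pd.DataFrame):
        missing = [n for n in feature_names if n not in X.columns]
        if missing:
            raise SchemaError(f"missing feature column(s) {missing}")
        return X[feature_names].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.shape[1] != len(feature_names):
        raise SchemaError(
            f"expected {len(feature_names)} feature columns, got {X.shape[1]}"
        )
    return X


def train_risk_model(
    kind: str,
    X,
    y,
    seed: int = 0,
    feature_names: list[str] | None = None,
    config: ModelConfig = ModelConfig(),
) -> RiskModel:
    """Fit one classifier kind on a training matrix. Deterministic given seed."""
    y = np.asarray(y).astype(int)
    if isinstance(X, pd.DataFrame) and feature_names is None:
        feature_names = list(X.columns)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(np.asarray(X).shape[1])]
    if len(np.unique(y)) < 2:
        raise TrainingError("training labels contain a single class")
    mat = _as_matrix(X, feature_names)
    est = _build_estimator(kind, y, seed, config)
    est.fit(mat, y)
    return RiskModel(kind=kind, feature_names=list(feature_names), estimator=est, seed=seed)


def score(model: RiskModel, X) -> np.ndarray:
    """Risk scores in [0, 1], one per case; columns are matched by name."""
    mat = _as_matrix(X, model.feature_names)
    out = model.estimator.predict_proba(mat)[:, 1]
    return np.clip(out.astype(float), 0.0, 1.0)


@dataclass
class FusionModel:
    """Logistic combiner of the tumor- and pancreas-model score channels."""

    combiner: LogisticRegression

    @property
    def coefficients(self) -> np.ndarray:
        return self.combiner.coef_[0].copy()

    @property
    def intercept(self) -> float:
        return float(self.combiner.intercept_[0])


def train_fusion(tum_scores, panc_scores, y) -> FusionModel:
    """Fit the two-input logistic combiner on out-of-fold channel scores."""
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise TrainingError("fusion training labels contain a single class")
    Z = np.column_stack([np.asarray(tum_scores, float), np.asarray(panc_scores, float)])
    lr = LogisticRegression(C=1.0, class_weight="balanced", max_iter=2000)
    lr.fit(Z, y)
    return FusionModel(combiner=lr)


def fuse(model: FusionModel, tum_scores, panc_scores) -> np.ndarray:
    Z = np.column_stack([np.asarray(tum_scores, float), np.asarray(panc_scores, float)])
    return np.clip(model.combiner.predict_proba(Z)[:, 1].astype(float), 0.0, 1.0)
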