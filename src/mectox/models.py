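"""Regression model zoo, cross-validation protocol and error metrics.

Four classical regressors are compared for per-toxicant concentration
prediction: support-vector regression (RBF kernel), k-nearest neighbours
(k = 200, Euclidean), partial least squares (2 components) and a random
forest (100 trees).  One independent single-output model is trained per
toxicant; evaluation uses ten-fold cross-validation with the fold
assignment seeded at 42, and metrics (MAE, RMSE, R²) are computed on the
pooled out-of-fold predictions.

Features are z-scored inside each training fold for the scale-sensitive
models (SVM, KNN, PLS); trees are scale-free and consume raw features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

__all__ = [
    "MODEL_KINDS",
    "ModelSpec",
    "mae",
    "rmse",
    "r_squared",
    "make_estimator",
    "train_predict_cv",
    "score_table",
    "compare_models",
    "raw_trace_matrix",
]

MODEL_KINDS = ("svm", "knn", "pls", "rf")


# -- error metrics ----------------------------------------------------------

def _paired(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    yt = np.asarray(y_true, dtype=float).ravel()
    yp = np.asarray(y_pred, dtype=float).ravel()
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    if yt.size == 0:
        raise ValueError("empty prediction set")
    return yt, yp


def mae(y_true, y_pred) -> float:
    """Mean absolute error: (1/n) * sum |ŷ_i − y_i|."""
    yt, yp = _paired(y_true, y_pred)
    return float(np.mean(np.abs(yp - yt)))


def rmse(y_true, y_pred) -> float:
    """Root mean square error: sqrt((1/n) * sum (ŷ_i − y_i)²)."""
    yt, yp = _paired(y_true, y_pred)
    return float(np.sqrt(np.mean((yp - yt) ** 2)))


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot; negative when the
    predictions explain less variance than the mean of the observations."""
    yt, yp = _paired(y_true, y_pred)
    ss_tot = float(np.sum((yt - yt.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R² undefined: y_true has zero variance")
    return float(1.0 - np.sum((yp - yt) ** 2) / ss_tot)


# -- model specs ------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """One algorithm with the fixed study hyperparameters.

    SVM pins its nominally "default" settings explicitly (C = 1,
    epsilon = 0.1, gamma = 1/(d·var)) so results cannot drift with
    library versions.
    """

    kind: str
    seed: int = 42
    cv_folds: int = 10
    hyperparams: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; "
                             f"expected one of {MODEL_KINDS}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def with_seed(self, seed: int) -> "ModelSpec":
        return replace(self, seed=seed)


def default_specs(seed: int = 42, cv_folds: int = 10) -> list[ModelSpec]:
    return [ModelSpec(kind, seed=seed, cv_folds=cv_folds) for kind in MODEL_KINDS]


def make_estimator(spec: ModelSpec, n_train: int | None = None):
    """Build the sklearn estimator for a spec.

    ``n_train`` lets KNN clamp k = 200 to the training-fold size (with a
    warning) instead of failing on small datasets.
    """
    hp = dict(spec.hyperparams)
    if spec.kind == "svm":
        est = SVR(kernel="rbf", C=hp.get("C", 1.0),
                  epsilon=hp.get("epsilon", 0.1), gamma=hp.get("gamma", "scale"))
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    if spec.kind == "knn":
        k = int(hp.get("n_neighbors", 200))
        if n_train is not None and k > n_train:
            warnings.warn(
                f"KNN k={k} exceeds training size {n_train}; clamping to {n_train}")
            k = n_train
        est = KNeighborsRegressor(n_neighbors=k, metric="euclidean")
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    if spec.kind == "pls":
        est = PLSRegression(n_components=int(hp.get("n_components", 2)))
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    if spec.kind == "rf":
        return RandomForestRegressor(
            n_estimators=int(hp.get("n_estimators", 100)),
            random_state=spec.seed, n_jobs=hp.get("n_jobs", None))
    raise ValueError(f"unknown model kind {spec.kind!r}")


def _predict(est, X: np.ndarray) -> np.ndarray:
    return np.asarray(est.predict(X)).ravel()  # PLS returns (n, 1)


# -- cross-validated training ----------------------------------------------

def train_predict_cv(
    X, Y: pd.DataFrame, spec: ModelSpec
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Pooled out-of-fold predictions per toxicant.

    One single-output regressor per target column; folds assigned by a
    shuffled KFold seeded with ``spec.seed``.  Deterministic given
    (X, Y, spec).
    """
    X = np.asarray(X, dtype=float)
    Y = pd.DataFrame(Y)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y row counts differ")
    if np.isnan(X).any() or Y.isna().any().any():
        raise ValueError("missing values are not allowed")
    n = X.shape[0]
    if n < spec.cv_folds:
        raise ValueError(f"n={n} smaller than cv_folds={spec.cv_folds}")

    kf = KFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for col in Y.columns:
        y = Y[col].to_numpy(dtype=float)
        pred = np.empty(n)
        for train_idx, test_idx in kf.split(X):
            est = make_estimator(spec, n_train=len(train_idx))
            est.fit(X[train_idx], y[train_idx])
            pred[test_idx] = _predict(est, X[test_idx])
        out[str(col)] = (y, pred)
    return out


def score_table(
    predictions: Mapping[str, Mapping[str, tuple[np.ndarray, np.ndarray]]]
) -> pd.DataFrame:
    """Long score table (model, toxicant, mae, rmse, r2) from nested
    {model: {toxicant: (y_true, y_pred)}} predictions."""
    rows = []
    for model, per_tox in predictions.items():
        for tox, (yt, yp) in per_tox.items():
            rows.append({"model": model, "toxicant": tox,
                         "mae": mae(yt, yp), "rmse": rmse(yt, yp),
                         "r2": r_squared(yt, yp)})
    return pd.DataFrame(rows)


def compare_models(
    X, Y: pd.DataFrame, specs: Sequence[ModelSpec] | None = None
) -> tuple[pd.DataFrame, dict]:
    """Cross-validated comparison of several model specs on one dataset.

    Returns (scores, predictions) where scores is the long table of
    per-model, per-toxicant MAE/RMSE/R² on pooled out-of-fold predictions.
    """
    if specs is None:
        specs = default_specs()
    predictions = {spec.kind: train_predict_cv(X, Y, spec) for spec in specs}
    return score_table(predictions), predictions


# -- raw-trace baseline -----------------------------------------------------

def raw_trace_matrix(traces, n_samples: int = 26) -> pd.DataFrame:
    """Post-injection currents as a fixed-width matrix (direct-modelling
    baseline: the trace itself is the feature vector).

    Each trace is truncated to its first ``n_samples`` post-injection
    samples; shorter traces are an error.
    """
    rows, ids = [], []
    for tr in traces:
        _, y = tr.post_injection()
        if y.size < n_samples:
            raise ValueError(
                f"trace {tr.sample_id!r} has {y.size} post-injection samples, "
                f"need {n_samples}")
        rows.append(y[:n_samples])
        ids.append(tr.sample_id)
    df = pd.DataFrame(np.asarray(rows),
                      columns=[f"I_{i}" for i in range(n_samples)])
    df.insert(0, "sample_id", ids)
    return df
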