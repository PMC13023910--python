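"""Overfitting diagnostics: learning curves, split evaluation, OOB, importances.

Four complementary checks that a concentration regressor generalizes
rather than memorizes: (1) learning curves — train and validation RMSE
should converge as the training set grows; (2) a grouped train/test split
(replicates of one exposure condition never straddle the split) comparing
train vs test R²; (3) for random forests, agreement between the internal
out-of-bag (OOB) R² and the held-out test R²; (4) Gini feature
importances, which should be non-negative, sum to one, and concentrate on
mechanistically meaningful descriptors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.exceptions import NotFittedError
from sklearn.model_selection import (GroupShuffleSplit, KFold,
                                     train_test_split)
from sklearn.model_selection import learning_curve as _sk_learning_curve
from sklearn.utils.validation import check_is_fitted

from .models import ModelSpec, _predict, make_estimator, r_squared, rmse

__all__ = [
    "LearningCurve",
    "learning_curve",
    "train_test_split_eval",
    "oob_vs_test",
    "gini_importance",
    "validation_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LearningCurve:
    train_sizes: np.ndarray
    train_error: np.ndarray     # mean RMSE over folds
    train_error_sd: np.ndarray
    val_error: np.ndarray
    val_error_sd: np.ndarray

    def __post_init__(self) -> None:
        n = self.train_sizes.size
        for name in ("train_error", "train_error_sd", "val_error", "val_error_sd"):
            if getattr(self, name).size != n:
                raise ValueError("learning-curve arrays must have equal length")
        if np.any(np.diff(self.train_sizes) <= 0):
            raise ValueError("train_sizes must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "train_size": self.train_sizes,
            "train_rmse": self.train_error,
            "train_rmse_sd": self.train_error_sd,
            "val_rmse": self.val_error,
            "val_rmse_sd": self.val_error_sd,
        })


def learning_curve(
    X, y, spec: ModelSpec,
    sizes: Sequence[int] | None = None,
    seed: int = 42,
    cv: int = 5,
) -> LearningCurve:
    """Train/validation RMSE as a function of training-set size.

    For each size a seeded subsample of the training folds is fitted and
    scored on the held-out fold; means and sds are over the ``cv`` folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    max_train = int(np.floor(len(y) * (cv - 1) / cv))
    if sizes is None:
        sizes = np.unique(np.geomspace(50, max_train, 6).astype(int))
    sizes = np.asarray(sorted(int(s) for s in sizes))
    if np.any(sizes < 10):
        raise ValueError("learning-curve sizes must be >= 10")
    if sizes.max() > max_train:
        raise ValueError(f"max size {sizes.max()} exceeds training rows {max_train}")

    folds = KFold(n_splits=cv, shuffle=True, random_state=seed)
    abs_sizes, train_scores, val_scores = _sk_learning_curve(
        make_estimator(spec, n_train=int(sizes.min())), X, y,
        train_sizes=sizes, cv=folds,
        scoring="neg_root_mean_squared_error", shuffle=True, random_state=seed)
    return LearningCurve(
        train_sizes=abs_sizes,
        train_error=(-train_scores).mean(axis=1),
        train_error_sd=(-train_scores).std(axis=1),
        val_error=(-val_scores).mean(axis=1),
        val_error_sd=(-val_scores).std(axis=1),
    )


def _grouped_split(n: int, groups, test_frac: float, seed: int):
    idx = np.arange(n)
    if groups is not None:
        groups = np.asarray(groups)
        _, counts = np.unique(groups, return_counts=True)
        if np.all(counts == 1):
            warnings.warn("every condition has a single replicate; grouped "
                          "split degenerates to a random split")
            groups = None
    if groups is None:
        return train_test_split(idx, test_size=test_frac, random_state=seed)
    gss = GroupShuffleSplit(n_splits=1, test_size=test_frac, random_state=seed)
    train_idx, test_idx = next(gss.split(idx, groups=groups))
    return train_idx, test_idx


def train_test_split_eval(
    X, Y: pd.DataFrame, spec: ModelSpec,
    groups=None, test_frac: float = 0.2, seed: int = 42,
) -> dict[str, tuple[float, float]]:
    """Per-toxicant (R²_train, R²_test) under a replicate-safe split.

    When ``groups`` labels exposure conditions, all replicates of one
    condition land on the same side of the split, so the test score
    reflects unseen conditions rather than sibling replicates.
    """
    if not 0 < test_frac < 1:
        raise ValueError("test_frac must be in (0, 1)")
    X = np.asarray(X, dtype=float)
    Y = pd.DataFrame(Y)
    train_idx, test_idx = _grouped_split(X.shape[0], groups, test_frac, seed)
    out: dict[str, tuple[float, float]] = {}
    for col in Y.columns:
        y = Y[col].to_numpy(dtype=float)
        est = make_estimator(spec, n_train=len(train_idx))
        est.fit(X[train_idx], y[train_idx])
        out[str(col)] = (
            r_squared(y[train_idx], _predict(est, X[train_idx])),
            r_squared(y[test_idx], _predict(est, X[test_idx])),
        )
    return out


def _oob_predictions(rf: RandomForestRegressor, X: np.ndarray, y: np.ndarray):
    """Out-of-bag prediction per training sample, plus coverage counts.

    A sample's OOB prediction averages only the trees whose bootstrap
    excluded it; samples in every tree's bootstrap have no OOB prediction.
    """
    try:  # sklearn internals for the exact per-tree bootstrap masks
        import inspect
        from sklearn.ensemble._forest import (_generate_unsampled_indices,
                                              _get_n_samples_bootstrap)
        n = X.shape[0]
        if "sample_weight" in inspect.signature(_get_n_samples_bootstrap).parameters:
            n_boot = _get_n_samples_bootstrap(n, rf.max_samples, None)

            def _unsampled(state):
                return _generate_unsampled_indices(state, n, n_boot, None)
        else:  # older signature
            n_boot = _get_n_samples_bootstrap(n, rf.max_samples)

            def _unsampled(state):
                return _generate_unsampled_indices(state, n, n_boot)
        total = np.zeros(n)
        counts = np.zeros(n, dtype=int)
        for tree in rf.estimators_:
            unsampled = _unsampled(tree.random_state)
            if unsampled.size:
                total[unsampled] += tree.predict(X[unsampled])
                counts[unsampled] += 1
        pred = np.full(n, np.nan)
        covered = counts > 0
        pred[covered] = total[covered] / counts[covered]
        return pred, counts
    except ImportError:  # pragma: no cover - fallback for other versions
        from sklearn.base import clone
        rf2 = clone(rf).set_params(oob_score=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rf2.fit(X, y)
        return rf2.oob_prediction_, np.ones(X.shape[0], dtype=int)


def oob_vs_test(
    X, y, spec: ModelSpec,
    groups=None, test_frac: float = 0.2, seed: int = 42,
) -> tuple[float, float, float]:
    """(OOB R², test R², |gap|) for a random forest.

    The forest is fitted on the training side of a random split; its OOB
    score (from samples excluded from each tree's bootstrap) is compared
    with the held-out R².  Samples with no OOB prediction are excluded and
    their count logged.  Both sides of this comparison are replicate-level
    scores — OOB resampling operates on samples, not exposure conditions —
    so the split here is deliberately ungrouped; pass ``groups`` to compare
    OOB against the stricter condition-level test score instead.
    """
    if spec.kind != "rf":
        raise ValueError("OOB diagnostics are defined for random forests only")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    train_idx, test_idx = _grouped_split(X.shape[0], groups, test_frac, seed)
    rf = make_estimator(spec, n_train=len(train_idx))
    rf.fit(X[train_idx], y[train_idx])

    oob_pred, counts = _oob_predictions(rf, X[train_idx], y[train_idx])
    covered = counts > 0
    n_undef = int((~covered).sum())
    if n_undef:
        logger.info("OOB undefined for %d/%d training samples (excluded)",
                    n_undef, len(train_idx))
    oob_score = r_squared(y[train_idx][covered], oob_pred[covered])
    test_score = r_squared(y[test_idx], _predict(rf, X[test_idx]))
    return oob_score, test_score, abs(oob_score - test_score)


def gini_importance(
    fitted_rf: RandomForestRegressor,
    feature_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Normalized mean impurity-decrease importances, descending.

    Returns a (feature, importance, rank) table; importances are
    non-negative and sum to 1.
    """
    try:
        check_is_fitted(fitted_rf)
    except NotFittedError as exc:
        raise ValueError("gini_importance requires a fitted forest") from exc
    imp = np.asarray(fitted_rf.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(imp.size)]
    if len(feature_names) != imp.size:
        raise ValueError("feature_names length mismatch")
    df = (pd.DataFrame({"feature": list(feature_names), "importance": imp})
          .sort_values("importance", ascending=False, kind="mergesort")
          .reset_index(drop=True))
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def validation_report(
    X, Y: pd.DataFrame,
    feature_names: Sequence[str],
    groups=None,
    spec: ModelSpec | None = None,
    seed: int = 42,
    sizes: Sequence[int] | None = None,
) -> dict:
    """Full diagnostics bundle for the forest model, per toxicant."""
    if spec is None:
        spec = ModelSpec("rf", seed=seed)
    X = np.asarray(X, dtype=float)
    Y = pd.DataFrame(Y)
    split_scores = train_test_split_eval(X, Y, spec, groups=groups, seed=seed)
    report: dict = {"model": spec.kind, "toxicants": {}}
    for col in Y.columns:
        y = Y[col].to_numpy(dtype=float)
        curve = learning_curve(X, y, spec, sizes=sizes, seed=seed)
        oob, test_r2, gap = oob_vs_test(X, y, spec, seed=seed)
        rf = make_estimator(spec, n_train=X.shape[0])
        rf.fit(X, y)
        imp = gini_importance(rf, feature_names)
        r2_train, r2_test_split = split_scores[str(col)]
        report["toxicants"][str(col)] = {
            "learning_curve": curve.to_frame().to_dict(orient="list"),
            "r2_train": r2_train,
            "r2_test": r2_test_split,
            "oob_score": oob,
            "oob_test_r2": test_r2,
            "oob_test_gap": gap,
            "gini_importance": imp.set_index("feature")["importance"].to_dict(),
        }
    return report
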