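"""Model/Results interface for concentration regression.

`ConcentrationModel` bundles a feature matrix, the per-toxicant ppm
targets and the evaluation protocol; `fit()` runs the cross-validated
training and returns a `ConcentrationResults` with the pooled out-of-fold
scores, full-data estimators, and the overfitting diagnostics hanging off
it (learning curves, grouped split evaluation, OOB agreement, Gini
importances, prediction plots).

    >>> model = ConcentrationModel.from_dataframes(features, truth)
    >>> res = model.fit()
    >>> print(res.summary())
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import validation as _validation
from .models import (ModelSpec, _predict, default_specs, make_estimator,
                     score_table, train_predict_cv)

__all__ = ["ConcentrationModel", "ConcentrationResults"]


class ConcentrationModel:
    """Per-toxicant concentration regression on engineered trace features.

    Parameters
    ----------
    X : array-like, shape (n_samples, n_features)
        Feature matrix (the 22 engineered descriptors, or a raw-trace
        matrix for the direct baseline).
    Y : DataFrame, shape (n_samples, n_toxicants)
        True concentrations in ppm, one column per toxicant.
    spec : ModelSpec
        Algorithm and protocol (default: random forest, 100 trees,
        10-fold CV seeded at 42).
    groups : array-like, optional
        Exposure-condition labels used by the diagnostics so replicates
        never straddle a train/test split.
    """

    def __init__(self, X, Y, spec: ModelSpec | None = None,
                 feature_names: Sequence[str] | None = None,
                 groups=None):
        self.X = np.asarray(X, dtype=float)
        self.Y = pd.DataFrame(Y)
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y row counts differ")
        self.spec = spec or ModelSpec("rf")
        if feature_names is None:
            feature_names = [f"x{i}" for i in range(self.X.shape[1])]
        if len(feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length mismatch")
        self.feature_names = list(feature_names)
        self.groups = None if groups is None else np.asarray(groups)

    @classmethod
    def from_dataframes(
        cls,
        features: pd.DataFrame,
        truth: pd.DataFrame,
        spec: ModelSpec | None = None,
        target_prefix: str = "ppm_",
        group_cols: Sequence[str] = ("setup_id", "ec_level"),
    ) -> "ConcentrationModel":
        """Join a feature table and a ground-truth table on sample_id.

        Target columns are those starting with ``target_prefix`` in
        ``truth``; condition groups are built from ``group_cols`` when
        present (used by the replicate-safe diagnostics).
        """
        f = features.set_index("sample_id")
        t = truth.set_index("sample_id")
        merged = f.join(t, how="inner", lsuffix="", rsuffix="_truth")
        if len(merged) == 0:
            raise ValueError("no overlapping sample_ids between tables")
        target_cols = [c for c in t.columns if c.startswith(target_prefix)]
        if not target_cols:
            raise ValueError(f"no target columns with prefix {target_prefix!r}")
        feat_cols = [c for c in features.columns if c != "sample_id"]
        groups = None
        if all(c in merged.columns for c in group_cols):
            groups = merged[list(group_cols)].astype(str).agg("|".join, axis=1)
        return cls(merged[feat_cols], merged[target_cols], spec=spec,
                   feature_names=feat_cols, groups=groups)

    def fit(self) -> "ConcentrationResults":
        """Run the cross-validation protocol and fit full-data estimators."""
        predictions = train_predict_cv(self.X, self.Y, self.spec)
        estimators = {}
        for col in self.Y.columns:
            est = make_estimator(self.spec, n_train=self.X.shape[0])
            est.fit(self.X, self.Y[col].to_numpy(dtype=float))
            estimators[str(col)] = est
        return ConcentrationResults(self, predictions, estimators)


class ConcentrationResults:
    """Fitted results: pooled out-of-fold scores plus diagnostics."""

    def __init__(self, model: ConcentrationModel,
                 predictions: Mapping[str, tuple[np.ndarray, np.ndarray]],
                 estimators: Mapping[str, object]):
        self.model = model
        self.predictions = dict(predictions)
        self.estimators = dict(estimators)
        self.scores = score_table({model.spec.kind: self.predictions}).drop(
            columns="model")

    # -- prediction ---------------------------------------------------------

    def predict(self, X) -> pd.DataFrame:
        """Predict concentrations for new feature rows (full-data fits)."""
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(
            {tox: _predict(est, X) for tox, est in self.estimators.items()})

    # -- diagnostics --------------------------------------------------------

    def learning_curve(self, toxicant: str, sizes=None, seed: int | None = None,
                       cv: int = 5) -> _validation.LearningCurve:
        m = self.model
        return _validation.learning_curve(
            m.X, m.Y[toxicant], m.spec, sizes=sizes,
            seed=m.spec.seed if seed is None else seed, cv=cv)

    def train_test_split_eval(self, test_frac: float = 0.2,
                              seed: int | None = None):
        m = self.model
        return _validation.train_test_split_eval(
            m.X, m.Y, m.spec, groups=m.groups, test_frac=test_frac,
            seed=m.spec.seed if seed is None else seed)

    def oob_vs_test(self, toxicant: str, test_frac: float = 0.2,
                    seed: int | None = None):
        m = self.model
        return _validation.oob_vs_test(
            m.X, m.Y[toxicant], m.spec, groups=m.groups, test_frac=test_frac,
            seed=m.spec.seed if seed is None else seed)

    def gini_importance(self, toxicant: str) -> pd.DataFrame:
        return _validation.gini_importance(
            self.estimators[toxicant], self.model.feature_names)

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary of the cross-validated scores."""
        m = self.model
        lines = [
            "Concentration regression results",
            "=" * 56,
            f"model: {m.spec.kind}   folds: {m.spec.cv_folds}   "
            f"seed: {m.spec.seed}   n: {m.X.shape[0]}   "
            f"features: {m.X.shape[1]}",
            "-" * 56,
            f"{'toxicant':<20}{'MAE':>10}{'RMSE':>10}{'R2':>10}",
        ]
        for _, row in self.scores.iterrows():
            lines.append(f"{row['toxicant']:<20}{row['mae']:>10.4f}"
                         f"{row['rmse']:>10.4f}{row['r2']:>10.4f}")
        lines.append("=" * 56)
        return "\n".join(lines)

    def plot_predictions(self, toxicant: str, ax=None):
        """Predicted-vs-true scatter of the pooled out-of-fold predictions."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        yt, yp = self.predictions[toxicant]
        ax.scatter(yt, yp, s=8, alpha=0.5)
        lim = [min(yt.min(), yp.min()), max(yt.max(), yp.max())]
        ax.plot(lim, lim, "k--", lw=1)
        ax.set_xlabel("true concentration (ppm)")
        ax.set_ylabel("predicted concentration (ppm)")
        ax.set_title(f"{self.model.spec.kind}: {toxicant}")
        return ax


def compare(X, Y, specs=None, feature_names=None, groups=None) -> pd.DataFrame:
    """Fit one ConcentrationModel per spec; long score table with a
    'model' column (the four-algorithm comparison)."""
    frames = []
    for spec in (specs or default_specs()):
        res = ConcentrationModel(X, Y, spec=spec, feature_names=feature_names,
                                 groups=groups).fit()
        sc = res.scores.copy()
        sc.insert(0, "model", spec.kind)
        frames.append(sc)
    return pd.concat(frames, ignore_index=True)
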