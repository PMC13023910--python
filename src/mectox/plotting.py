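"""Diagnostic plots for validation outputs (learning curves, importances)."""

from __future__ import annotations

import pandas as pd

from .validation import LearningCurve


def plot_learning_curve(curve: LearningCurve, ax=None, title: str = ""):
    """Train vs validation RMSE against training-set size."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.plot(curve.train_sizes, curve.train_error, "o-", label="training RMSE")
    ax.fill_between(curve.train_sizes,
                    curve.train_error - curve.train_error_sd,
                    curve.train_error + curve.train_error_sd, alpha=0.2)
    ax.plot(curve.train_sizes, curve.val_error, "s-", label="validation RMSE")
    ax.fill_between(curve.train_sizes,
                    curve.val_error - curve.val_error_sd,
                    curve.val_error + curve.val_error_sd, alpha=0.2)
    ax.set_xlabel("training samples")
    ax.set_ylabel("RMSE (ppm)")
    if title:
        ax.set_title(title)
    ax.legend()
    return ax


def plot_importances(table: pd.DataFrame, ax=None, top: int = 22,
                     title: str = ""):
    """Horizontal bar chart of Gini importances (descending)."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 5.5))
    sub = table.nsmallest(top, "rank").iloc[::-1]
    ax.barh(sub["feature"], sub["importance"])
    ax.set_xlabel("Gini importance")
    if title:
        ax.set_title(title)
    return ax
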