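"""Feature engineering: 22 signal descriptors of one exposure trace.

Each current–time record is reduced to 22 indicators with direct
electrochemical/toxicological meaning: extrema and their timing, relative
current change ΔI/I0 (overall inhibition intensity), secant slopes
(response kinetics), the curve integral (cumulative electron transfer),
smoothed-derivative extrema (fastest decline/rise), and two binary
event flags — ``up`` for the early stress transient and ``back`` for
recovery after the decline phase.

All descriptors are computed on the post-injection window only; the
pre-injection window provides the baseline current I0 and its noise level
sigma0, which calibrate the event-flag thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dataclass_fields
from typing import Iterable

import numpy as np
import pandas as pd

from .synth import CurrentTrace

__all__ = [
    "FEATURE_COLUMNS",
    "BaselineEstimate",
    "FeatureVector",
    "estimate_baseline",
    "extract_features",
    "featurize_dataset",
]

#: Canonical feature order (22 columns).
FEATURE_COLUMNS: tuple[str, ...] = (
    "i_max", "i_min", "delta_i", "delta_i_rel",
    "t_imax", "t_imin", "delta_t", "k_secant",
    "i_rise", "i_drop", "k_max0", "k_min0",
    "i_end", "duration", "k_all", "up", "back",
    "integral", "d_max", "d_min", "t_dmax", "t_dmin",
)


@dataclass(frozen=True)
class BaselineEstimate:
    """Pre-injection baseline: current I0 (mA) and residual sd sigma0 (mA)."""

    i0: float
    sigma0: float

    def __post_init__(self) -> None:
        if not self.i0 > 0:
            raise ValueError(f"baseline current must be positive, got {self.i0}")
        if self.sigma0 < 0:
            raise ValueError("sigma0 must be non-negative")


@dataclass(frozen=True)
class FeatureVector:
    i_max: float
    i_min: float
    delta_i: float
    delta_i_rel: float
    t_imax: float
    t_imin: float
    delta_t: float
    k_secant: float
    i_rise: float
    i_drop: float
    k_max0: float
    k_min0: float
    i_end: float
    duration: float
    k_all: float
    up: int
    back: int
    integral: float
    d_max: float
    d_min: float
    t_dmax: float
    t_dmin: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dataclass_fields(self)}


assert tuple(f.name for f in dataclass_fields(FeatureVector)) == FEATURE_COLUMNS
assert len(FEATURE_COLUMNS) == 22


def estimate_baseline(trace: CurrentTrace, window_s: float = 60.0) -> BaselineEstimate:
    """Baseline current from the trailing pre-injection window.

    I0 is the mean of samples with time < injection_time within ``window_s``
    of the injection; sigma0 their sample sd.  If the record starts at
    injection (no pre-injection samples), I0 falls back to the first sample
    and sigma0 to 0.
    """
    mask = (trace.times < trace.injection_time) & (
        trace.times >= trace.injection_time - window_s)
    pre = trace.currents[mask]
    if pre.size == 0:
        return BaselineEstimate(float(trace.currents[0]), 0.0)
    sigma0 = float(np.std(pre, ddof=1)) if pre.size > 1 else 0.0
    return BaselineEstimate(float(np.mean(pre)), sigma0)


def moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with window truncation at the edges."""
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be a positive odd integer")
    h = window // 2
    n = y.size
    out = np.empty(n)
    for i in range(n):
        out[i] = y[max(0, i - h):min(n, i + h + 1)].mean()
    return out


def extract_features(
    trace: CurrentTrace,
    baseline: BaselineEstimate | None = None,
    smooth_window: int = 5,
    kappa: float = 3.0,
    up_window_s: float = 60.0,
) -> FeatureVector:
    """Compute the 22 descriptors of one trace.

    Extrema are taken over post-injection samples only, ties resolved to
    the earliest sample.  Times are reported in seconds since injection.
    Derivatives are central finite differences of a centered moving average
    (window ``smooth_window``).  The ``up``/``back`` flags fire when the
    raw early maximum (resp. a smoothed post-minimum sample) exceeds its
    reference by ``kappa * sigma0``.
    """
    if baseline is None:
        baseline = estimate_baseline(trace)
    i0, sigma0 = baseline.i0, baseline.sigma0

    t_rel, y = trace.post_injection()
    if t_rel.size < 3:
        raise ValueError("need at least 3 post-injection samples")

    imax_idx = int(np.argmax(y))
    imin_idx = int(np.argmin(y))
    i_max = float(y[imax_idx])
    i_min = float(y[imin_idx])
    t_imax = float(t_rel[imax_idx])
    t_imin = float(t_rel[imin_idx])
    delta_i = i_max - i_min
    delta_t = t_imax - t_imin
    k_secant = delta_i / delta_t if delta_t != 0 else 0.0
    i_rise = i_max - i0
    i_drop = i0 - i_min
    k_max0 = i_rise / t_imax if t_imax > 0 else 0.0
    k_min0 = (i_min - i0) / t_imin if t_imin > 0 else 0.0
    i_end = float(y[-1])
    duration = float(trace.times[-1] - trace.injection_time)
    k_all = (i_end - i0) / duration if duration > 0 else 0.0
    integral = float(np.trapezoid(y, t_rel))

    smoothed = moving_average(y, smooth_window)
    deriv = np.gradient(smoothed, t_rel)
    dmax_idx = int(np.argmax(deriv))
    dmin_idx = int(np.argmin(deriv))

    early = y[t_rel <= up_window_s]
    up = int(early.size > 0 and float(early.max()) > i0 + kappa * sigma0)
    after_min = smoothed[t_rel > t_imin]
    back = int(
        t_imin < duration
        and after_min.size > 0
        and float(after_min.max()) >= i_min + kappa * sigma0
    )

    return FeatureVector(
        i_max=i_max, i_min=i_min, delta_i=delta_i, delta_i_rel=delta_i / i0,
        t_imax=t_imax, t_imin=t_imin, delta_t=delta_t, k_secant=k_secant,
        i_rise=i_rise, i_drop=i_drop, k_max0=k_max0, k_min0=k_min0,
        i_end=i_end, duration=duration, k_all=k_all, up=up, back=back,
        integral=integral,
        d_max=float(deriv[dmax_idx]), d_min=float(deriv[dmin_idx]),
        t_dmax=float(t_rel[dmax_idx]), t_dmin=float(t_rel[dmin_idx]),
    )


def featurize_dataset(
    traces: Iterable[CurrentTrace],
    smooth_window: int = 5,
    kappa: float = 3.0,
    baseline_window_s: float = 60.0,
) -> pd.DataFrame:
    """Feature table: one row per trace, 22 columns, keyed by sample_id."""
    rows = []
    ids: list[str] = []
    for trace in traces:
        baseline = estimate_baseline(trace, window_s=baseline_window_s)
        fv = extract_features(trace, baseline, smooth_window=smooth_window,
                              kappa=kappa)
        ids.append(trace.sample_id)
        rows.append(fv.as_dict())
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample_id(s): {dupes[:5]}")
    df = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
    df.insert(0, "sample_id", ids)
    return df
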