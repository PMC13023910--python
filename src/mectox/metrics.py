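"""Mixture-toxicity statistics: response indices, Interaction Index, calibrations.

The primary toxicity response of a trace is the relative current change
ΔI/I0.  For a mixture, concentration addition predicts the response as the
sum of the single-toxicant responses at the component concentrations
actually present in the mixture; the Interaction Index

    II = (ΔI/I0)_mixture / sum_j (ΔI/I0)_single,j

quantifies the departure: II > 1 synergy, II < 1 antagonism, II = 1
additivity.  Fixed-time responses (I0 − I(t))/I0 at 30, 60 and 300 s are
fitted linearly against the EC gradient as a classical calibration check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import estimate_baseline
from .synth import CurrentTrace

__all__ = [
    "InteractionResult",
    "CalibrationFit",
    "response_at_times",
    "fixed_time_responses",
    "interaction_index",
    "single_response_table",
    "single_response_lookup",
    "mixture_interaction_table",
    "calibration_fit",
]

DEFAULT_RESPONSE_TIMES = (30.0, 60.0, 300.0)


@dataclass(frozen=True)
class InteractionResult:
    mixture_id: str
    ii: float
    mixture_response: float
    single_response_sum: float

    @property
    def classification(self) -> str:
        if self.ii > 1:
            return "synergy"
        if self.ii < 1:
            return "antagonism"
        return "additive"


@dataclass(frozen=True)
class CalibrationFit:
    time_s: float
    slope: float
    intercept: float
    r2: float


def response_at_times(
    trace: CurrentTrace,
    i0: float | None = None,
    times: Sequence[float] = DEFAULT_RESPONSE_TIMES,
) -> dict[float, float]:
    """Fixed-time inhibition responses (I0 − I(t'))/I0 at given t' (s).

    Each requested time maps to the nearest post-injection grid sample;
    on a 12 s grid 30 s is equidistant from 24 s and 36 s and resolves to
    the later sample (36 s).
    """
    if i0 is None:
        i0 = estimate_baseline(trace).i0
    t_rel, y = trace.post_injection()
    out = {}
    for t in times:
        # nearest grid sample, ties to the later one
        dist = np.abs(t_rel - t)
        best = np.flatnonzero(dist == dist.min())[-1]
        out[float(t)] = float((i0 - y[best]) / i0)
    return out


def fixed_time_responses(
    traces: Sequence[CurrentTrace],
    times: Sequence[float] = DEFAULT_RESPONSE_TIMES,
) -> pd.DataFrame:
    """Table of fixed-time responses, one row per trace."""
    rows = []
    for tr in traces:
        resp = response_at_times(tr, times=times)
        rows.append({"sample_id": tr.sample_id,
                     **{f"response_{int(t)}s": v for t, v in resp.items()}})
    return pd.DataFrame(rows)


def interaction_index(
    mixture_response: float,
    single_responses: Sequence[float],
    mixture_id: str = "",
) -> InteractionResult:
    """II = mixture response / sum of single-toxicant responses.

    Negative mixture responses (noise) are floored at 0; a non-positive
    denominator leaves II undefined and raises.
    """
    singles = [float(s) for s in single_responses]
    if any(s < 0 for s in singles):
        raise ValueError("single-toxicant responses must be non-negative")
    denom = float(sum(singles))
    if denom <= 0:
        raise ValueError("sum of single responses must be positive; II undefined")
    num = max(0.0, float(mixture_response))
    return InteractionResult(mixture_id, num / denom, num, denom)


def _is_single(components: str) -> bool:
    return "+" not in components


def single_response_table(
    manifest: pd.DataFrame,
    responses: Mapping[str, float] | pd.Series,
    response_name: str = "delta_i_rel",
) -> pd.DataFrame:
    """Mean single-toxicant response per (toxicant, ppm), from manifest rows.

    ``responses`` maps sample_id to the response value (e.g. the
    delta_i_rel column of the feature table).  A (0 ppm, 0 response)
    anchor is added per toxicant — zero dose gives zero response by
    definition — so mixture components below the lowest tested single
    concentration interpolate toward zero instead of clamping.
    """
    if isinstance(responses, pd.Series):
        responses = responses.to_dict()
    singles = manifest[manifest["components"].map(_is_single)]
    if singles.empty:
        raise ValueError("manifest contains no single-toxicant setups")
    rows = []
    for _, row in singles.iterrows():
        tox = row["components"]
        rows.append({
            "toxicant": tox,
            "ppm": float(row[f"ppm_{tox}"]),
            response_name: float(responses[row["sample_id"]]),
        })
    table = (pd.DataFrame(rows)
             .groupby(["toxicant", "ppm"], as_index=False)[response_name].mean())
    table = table.rename(columns={response_name: "response"})
    anchors = pd.DataFrame({"toxicant": table["toxicant"].unique()})
    anchors["ppm"] = 0.0
    anchors["response"] = 0.0
    mask = ~anchors["toxicant"].isin(table.loc[table["ppm"] == 0, "toxicant"])
    return (pd.concat([table, anchors[mask]], ignore_index=True)
            .sort_values(["toxicant", "ppm"]).reset_index(drop=True))


def single_response_lookup(
    table: pd.DataFrame, toxicant: str, ppm: float
) -> float:
    """Expected single-toxicant response at a concentration (ppm).

    Linear interpolation of the mean response between tabulated
    concentrations, clamped at the range ends.
    """
    sub = table[table["toxicant"] == toxicant]
    if sub.empty:
        raise KeyError(f"toxicant {toxicant!r} absent from single-response table")
    if sub["ppm"].nunique() < 2:
        raise ValueError(f"need >= 2 concentration levels for {toxicant!r}")
    sub = sub.sort_values("ppm")
    return float(np.interp(ppm, sub["ppm"].to_numpy(), sub["response"].to_numpy()))


def mixture_interaction_table(
    manifest: pd.DataFrame,
    responses: Mapping[str, float] | pd.Series,
    ppm_prefix: str = "ppm_",
) -> pd.DataFrame:
    """Interaction Index per mixture condition (setup_id × EC level).

    The mixture response is the replicate mean; the denominator sums the
    interpolated single-toxicant responses at each component's actual ppm
    in the mixture (the concentration-addition reference).
    """
    if isinstance(responses, pd.Series):
        responses = responses.to_dict()
    singles_table = single_response_table(manifest, responses)
    ppm_cols = [c for c in manifest.columns if c.startswith(ppm_prefix)]
    mixtures = manifest[~manifest["components"].map(_is_single)]
    rows = []
    for (setup_id, ec), grp in mixtures.groupby(["setup_id", "ec_level"]):
        mix_resp = float(np.mean([responses[sid] for sid in grp["sample_id"]]))
        first = grp.iloc[0]
        denom_terms = []
        for col in ppm_cols:
            ppm = float(first[col])
            if ppm > 0:
                denom_terms.append(
                    single_response_lookup(singles_table, col[len(ppm_prefix):], ppm))
        res = interaction_index(mix_resp, denom_terms,
                                mixture_id=f"{setup_id}|ec{ec}")
        rows.append({
            "mixture_id": res.mixture_id,
            "setup_id": setup_id,
            "ec_level": ec,
            "mixture_response": res.mixture_response,
            "single_response_sum": res.single_response_sum,
            "ii": res.ii,
            "classification": res.classification,
        })
    return pd.DataFrame(rows)


def calibration_fit(
    responses: Sequence[tuple[float, float]], time_s: float = float("nan")
) -> CalibrationFit:
    """OLS of response against EC level: slope, intercept, R².

    Constant responses give slope 0 and R² = 0 (no variance explained).
    """
    arr = np.asarray(responses, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("responses must be (ec, response) pairs")
    ec, resp = arr[:, 0], arr[:, 1]
    if np.unique(ec).size < 3:
        raise ValueError("need >= 3 distinct EC levels for a calibration fit")
    slope, intercept = np.polyfit(ec, resp, 1)
    fitted = slope * ec + intercept
    ss_res = float(np.sum((resp - fitted) ** 2))
    ss_tot = float(np.sum((resp - resp.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationFit(time_s=float(time_s), slope=float(slope),
                          intercept=float(intercept), r2=float(r2))


def calibration_table(
    manifest: pd.DataFrame,
    traces: Sequence[CurrentTrace],
    times: Sequence[float] = DEFAULT_RESPONSE_TIMES,
) -> pd.DataFrame:
    """Per-setup linear calibrations of fixed-time response vs EC level."""
    resp = fixed_time_responses(traces, times=times).set_index("sample_id")
    merged = manifest.set_index("sample_id").join(resp, how="inner")
    rows = []
    for setup_id, grp in merged.groupby("setup_id"):
        if grp["ec_level"].nunique() < 3:
            warnings.warn(f"setup {setup_id}: fewer than 3 EC levels, skipped")
            continue
        for t in times:
            pairs = list(zip(grp["ec_level"], grp[f"response_{int(t)}s"]))
            fit = calibration_fit(pairs, time_s=t)
            rows.append({"setup_id": setup_id, "time_s": t, "slope": fit.slope,
                         "intercept": fit.intercept, "r2": fit.r2})
    return pd.DataFrame(rows)
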