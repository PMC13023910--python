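"""Synthetic chronoamperometric trace generator with toxicokinetic structure.

A microbial electrochemical sensor produces a current–time (I–t) record per
exposure: a stable baseline current I0, then — after toxicant injection —
an optional transient stress rise, a dose-dependent exponential decline
toward an inhibition plateau, and (at sub-threshold doses) a partial
recovery as the biofilm adapts.  The noise-free model is

    I(t)  = I0                                          for t < t_inj
    I(t') = I0 * [1 + A * (t'/tau_up) * e^(1 - t'/tau_up) * 1(stress)]
               * [1 - f * (1 - e^(-t'/tau_dec))]
            + 1(recovery) * r * I0 * (1 - e^(-max(0, t' - t_r)/tau_rec))

with t' = t - t_inj and inhibition fraction f = min(beta * dose, f_cap).
The effective dose is a concentration-addition surrogate scaled by a
mixture interaction factor lambda (>1 synergy, <1 antagonism):

    dose = lambda * 10 * sum_j ppm_j / c_max_j        (EC units)

Toxicants differ in their kinetics: heavy metals act fast (short decline
timescale), organics and antibiotics more slowly, and each toxicant drives
the stress transient with its own amplitude coefficient.  Mixture kinetics
are toxic-unit-weighted averages of the component timescales.  These
toxicant-specific signatures are what makes per-component concentrations
recoverable from a single trace at all.

i.i.d. Gaussian noise (clipped at 5 sd) is added pointwise; every trace is
reproducible bit-for-bit from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import DEFAULT_PANEL, Toxicant

__all__ = [
    "CurrentTrace",
    "SimulationParams",
    "effective_dose",
    "simulate_trace",
    "simulate_dataset",
    "default_lambda_map",
    "traces_to_frame",
    "frame_to_traces",
]

# Per-toxicant kinetic signatures.  Each toxicant's mode of action gets a
# distinct fingerprint: decline timescale (metals act fast, the antibiotic
# slowly), stress-transient amplitude per EC unit (organics provoke the
# strongest metabolic upregulation) and stress peak time.  Mixtures take
# toxic-unit-weighted averages.
DEFAULT_TAU_DECLINE: dict[str, float] = {
    "formaldehyde": 110.0,
    "tetracycline": 250.0,
    "silver_nitrate": 25.0,
    "copper_sulfate": 60.0,
}

# Stress-transient amplitude per EC unit of each toxicant (dimensionless).
DEFAULT_STRESS_AMP: dict[str, float] = {
    "formaldehyde": 0.015,
    "tetracycline": 0.002,
    "silver_nitrate": 0.005,
    "copper_sulfate": 0.010,
}

# Stress peak time (s): when the transient metabolic upregulation peaks.
DEFAULT_TAU_UP: dict[str, float] = {
    "formaldehyde": 30.0,
    "tetracycline": 45.0,
    "silver_nitrate": 15.0,
    "copper_sulfate": 66.0,
}

# Recovery (adaptation) capacity: fraction of I0 recoverable at vanishing
# dose.  Degradable organics allow strong metabolic adaptation, the
# antibiotic some, dissolved metals essentially none.
DEFAULT_RECOVERY_AMP: dict[str, float] = {
    "formaldehyde": 0.10,
    "tetracycline": 0.06,
    "silver_nitrate": 0.0,
    "copper_sulfate": 0.02,
}


@dataclass
class CurrentTrace:
    """One I–t exposure record on a uniform sampling grid."""

    sample_id: str
    times: np.ndarray          # s, uniform grid
    currents: np.ndarray       # mA
    injection_time: float      # s
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.currents.shape:
            raise ValueError("times and currents must be 1-D arrays of equal length")
        steps = np.diff(self.times)
        if len(steps) and (steps.min() <= 0):
            raise ValueError("times must be strictly increasing")
        if len(steps) and not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
            raise ValueError("times must be on a uniform grid")
        if not np.all(np.isfinite(self.currents)):
            raise ValueError("currents must be finite")
        if np.any(self.currents <= 0):
            raise ValueError("currents must be positive")
        if int(np.sum(self.times >= self.injection_time)) < 3:
            raise ValueError("need at least 3 post-injection samples")

    @property
    def step(self) -> float:
        return float(self.times[1] - self.times[0])

    def post_injection(self) -> tuple[np.ndarray, np.ndarray]:
        """(time since injection, current) for samples at or after injection."""
        mask = self.times >= self.injection_time
        return self.times[mask] - self.injection_time, self.currents[mask]


def _as_callable(p: float | Callable[[float], float]) -> Callable[[float], float]:
    if callable(p):
        return p
    return lambda dose, _p=float(p): _p


@dataclass
class SimulationParams:
    """Generative parameters of the trace model.

    The defaults define the study conditions used throughout: baseline
    current ~1 mA, inhibition slope beta = 0.02 per EC unit (a single
    toxicant at its maximum concentration, dose 10, inhibits 20% of the
    current), toxicant-specific decline timescales and stress amplitudes,
    recovery below 3 EC units, and 1% measurement noise.
    """

    panel: Sequence[Toxicant] = DEFAULT_PANEL
    i0_mean: float = 1.0            # mA
    i0_sd: float = 0.01             # mA, trace-to-trace baseline variation
    beta: float = 0.02              # inhibition fraction per EC unit
    f_cap: float = 0.95             # max inhibition fraction
    tau_decline: float | Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TAU_DECLINE))  # s
    stress_prob: float | Callable[[float], float] = 1.0
    stress_amp: float | Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STRESS_AMP))
    stress_amp_cap: float = 0.5
    tau_up: float | Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TAU_UP))  # s, stress-pulse timescale
    recovery_threshold: float = 5.0  # EC units; recovery below this dose
    recovery_amp: float | Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RECOVERY_AMP))
    recovery_delay: float = 150.0   # s after injection before recovery onset
    tau_rec: float = 80.0           # s
    tau_jitter: float = 0.0         # lognormal sd of per-trace timescale factor
    lambda_map: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0003        # mA
    baseline_duration: float = 60.0  # s before injection
    exposure_duration: float = 300.0  # s after injection
    dt: float = 12.0                # s sampling interval

    def __post_init__(self) -> None:
        if not self.tau_rec > 0 or not self.dt > 0:
            raise ValueError("tau_rec and dt must be positive")
        for name, val in (("tau_decline", self.tau_decline),
                          ("tau_up", self.tau_up)):
            taus = val.values() if isinstance(val, Mapping) else [val]
            if any(t <= 0 for t in taus):
                raise ValueError(f"{name} timescales must be positive")
        if not (0 <= self.f_cap < 1):
            raise ValueError("f_cap must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if any(lam <= 0 for lam in self.lambda_map.values()):
            raise ValueError("interaction factors lambda must be positive")
        if self.i0_mean <= 0:
            raise ValueError("i0_mean must be positive")

    @classmethod
    def additive_reference(cls, **overrides) -> "SimulationParams":
        """Noise-free, inhibition-only parameters with shared kinetics.

        Used to check concentration-addition arithmetic (interaction-index
        recovery): no stress transient, no recovery, no noise, and one
        common decline timescale so mixture and single-toxicant exposures
        share the same saturation factor.
        """
        base = dict(
            i0_sd=0.0, noise_sd=0.0, stress_prob=0.0, stress_amp=0.0,
            recovery_amp=0.0, tau_decline=80.0, tau_up=36.0,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def stress_coupled(cls, **overrides) -> "SimulationParams":
        """Configuration where the stress transient carries the toxicant
        identity: decline and stress timescales are shared across toxicants
        (with per-trace latency jitter emulating run-to-run biofilm
        variability), recovery is off, and each toxicant drives the
        transient with a distinct dose-coupled amplitude.  Under these
        conditions the current-increment feature (I_max − I0) is the one
        clean reader of the stress amplitude, which is what makes it a
        universally high-importance predictor.  Amplitude coefficients are
        keyed to the default panel; override ``stress_amp`` for others.
        """
        base = dict(
            tau_decline=80.0, tau_up=30.0, recovery_amp=0.0, tau_jitter=0.4,
            stress_amp={"formaldehyde": 0.040, "tetracycline": 0.010,
                        "silver_nitrate": 0.022, "copper_sulfate": 0.030},
        )
        base.update(overrides)
        return cls(**base)

    def with_lambda(self, lambda_map: Mapping[str, float]) -> "SimulationParams":
        return replace(self, lambda_map=dict(lambda_map))

    # -- per-composition helpers -------------------------------------------

    def _cmax(self) -> dict[str, float]:
        return {t.name: t.c_max for t in self.panel}

    def toxic_units(self, component_ppm: Mapping[str, float]) -> dict[str, float]:
        cmax = self._cmax()
        unknown = set(component_ppm) - set(cmax)
        if unknown:
            raise KeyError(f"unknown toxicants: {sorted(unknown)}")
        if any(v < 0 for v in component_ppm.values()):
            raise ValueError("ppm values must be non-negative")
        return {k: component_ppm[k] / cmax[k] for k in component_ppm}

    def _weighted_tau(self, tau: float | Mapping[str, float],
                      component_ppm: Mapping[str, float]) -> float:
        if not isinstance(tau, Mapping):
            return float(tau)
        tu = self.toxic_units(component_ppm)
        total = sum(tu.values())
        if total == 0:
            return float(np.mean(list(tau.values())))
        return sum(tau[k] * u for k, u in tu.items()) / total

    def effective_tau(self, component_ppm: Mapping[str, float]) -> float:
        """Toxic-unit-weighted decline timescale of a composition."""
        return self._weighted_tau(self.tau_decline, component_ppm)

    def effective_tau_up(self, component_ppm: Mapping[str, float]) -> float:
        """Toxic-unit-weighted stress-pulse timescale of a composition."""
        return self._weighted_tau(self.tau_up, component_ppm)

    def stress_amplitude(self, component_ppm: Mapping[str, float]) -> float:
        """Stress-transient amplitude: dose-coupled, toxicant-specific."""
        tu = self.toxic_units(component_ppm)
        if isinstance(self.stress_amp, Mapping):
            amp = sum(self.stress_amp.get(k, 0.0) * 10.0 * u for k, u in tu.items())
        else:
            amp = self.stress_amp * 10.0 * sum(tu.values())
        return min(amp, self.stress_amp_cap)

    def recovery_amplitude(self, component_ppm: Mapping[str, float],
                           dose: float) -> float:
        """Graded adaptation amplitude: the toxic-unit-weighted recovery
        capacity, fading linearly to zero at the recovery threshold.
        Capped at 80% of the inhibition plateau — adaptation restores part
        of the impaired electron transfer, never more than was lost."""
        if dose <= 0 or dose >= self.recovery_threshold:
            return 0.0
        cap = self._weighted_tau(self.recovery_amp, component_ppm)
        f = min(self.beta * dose, self.f_cap)
        return min(cap * (1.0 - dose / self.recovery_threshold), 0.8 * f)


def effective_dose(
    component_ppm: Mapping[str, float],
    panel: Sequence[Toxicant] = DEFAULT_PANEL,
    lam: float = 1.0,
) -> float:
    """Concentration-addition dose in EC units: lam * 10 * sum_j ppm_j/c_max_j."""
    cmax = {t.name: t.c_max for t in panel}
    unknown = set(component_ppm) - set(cmax)
    if unknown:
        raise KeyError(f"unknown toxicants: {sorted(unknown)}")
    if any(v < 0 for v in component_ppm.values()):
        raise ValueError("ppm values must be non-negative")
    return lam * 10.0 * sum(component_ppm[k] / cmax[k] for k in component_ppm)


def default_lambda_map(
    setups, seed: int = 42, low: float = 0.25, high: float = 1.8,
    pinned: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Interaction factors for a list of setups.

    Singles are additive by definition (lambda = 1).  Mixtures draw a
    log-uniform factor in [low, high], except for two pinned conditions
    reproducing the observed extremes of the real sensor: strong synergy
    (1.6) for the formaldehyde–tetracycline 2:1 mixture and strong
    antagonism (0.18) for the equal-ratio quaternary mixture.
    """
    rng = np.random.default_rng(seed)
    if pinned is None:
        pinned = {
            "formaldehyde+tetracycline@2:1": 1.6,
            "copper_sulfate+formaldehyde+silver_nitrate+tetracycline@1:1:1:1": 0.18,
        }
    out: dict[str, float] = {}
    for s in setups:
        if s.order == 1:
            out[s.setup_id] = 1.0
        elif s.setup_id in pinned:
            out[s.setup_id] = pinned[s.setup_id]
        else:
            out[s.setup_id] = float(np.exp(rng.uniform(np.log(low), np.log(high))))
    return out


def _manifest_ppm(row: Mapping, params: SimulationParams) -> dict[str, float]:
    cmax = params._cmax()
    ppm = {}
    for name in cmax:
        key = f"ppm_{name}"
        if key not in row:
            raise KeyError(f"manifest row missing column {key}")
        ppm[name] = float(row[key])
    return ppm


def _clean_curve(
    t_rel: np.ndarray, i0: float, f: float, tau_dec: float,
    stress_on: bool, amp: float, tau_up: float,
    recovery_on: bool, r: float, t_r: float, tau_rec: float,
) -> np.ndarray:
    stress = np.zeros_like(t_rel)
    if stress_on and amp > 0:
        stress = amp * (t_rel / tau_up) * np.exp(1.0 - t_rel / tau_up)
    decline = 1.0 - f * (1.0 - np.exp(-t_rel / tau_dec))
    curve = i0 * (1.0 + stress) * decline
    if recovery_on and r > 0:
        curve = curve + r * i0 * (1.0 - np.exp(-np.maximum(0.0, t_rel - t_r) / tau_rec))
    return curve


def simulate_trace(
    manifest_row: Mapping,
    params: SimulationParams,
    seed: int | Sequence[int] = 0,
) -> tuple[CurrentTrace, dict]:
    """Simulate one exposure trace; returns (trace, ground-truth record).

    Identical (manifest_row, params, seed) gives bit-identical currents.
    """
    rng = np.random.default_rng(seed)
    ppm = _manifest_ppm(manifest_row, params)
    setup_id = str(manifest_row.get("setup_id", ""))
    lam = float(params.lambda_map.get(setup_id, 1.0))
    dose = effective_dose(ppm, params.panel, lam)
    f = min(params.beta * dose, params.f_cap)
    tau_dec = params.effective_tau(ppm)
    tau_up = params.effective_tau_up(ppm)
    amp = params.stress_amplitude(ppm)

    # random draws in fixed order for reproducibility
    i0 = params.i0_mean + params.i0_sd * float(np.clip(rng.standard_normal(), -3, 3))
    i0 = max(i0, 0.05 * params.i0_mean)
    p_stress = _as_callable(params.stress_prob)(dose)
    stress_on = bool(dose > 0 and amp > 0 and rng.random() < p_stress)
    if params.tau_jitter > 0:
        # biological run-to-run variability of the response latency
        tau_up *= float(np.exp(params.tau_jitter
                               * np.clip(rng.standard_normal(), -3, 3)))
    rec_amp = params.recovery_amplitude(ppm, dose)
    recovery_on = bool(rec_amp > 0)

    n_pre = int(math.floor(params.baseline_duration / params.dt + 1e-9))
    n_post = int(math.floor(params.exposure_duration / params.dt + 1e-9)) + 1
    times = np.arange(n_pre + n_post) * params.dt
    t_inj = n_pre * params.dt
    t_rel = times[n_pre:] - t_inj

    clean = np.empty_like(times)
    clean[:n_pre] = i0
    clean[n_pre:] = _clean_curve(
        t_rel, i0, f, tau_dec, stress_on, amp, tau_up,
        recovery_on, rec_amp, params.recovery_delay, params.tau_rec)

    noise = params.noise_sd * np.clip(rng.standard_normal(times.size), -5, 5)
    currents = np.maximum(clean + noise, 1e-6)

    post_clean = clean[n_pre:]
    truth = {
        "sample_id": manifest_row.get("sample_id", ""),
        "setup_id": setup_id,
        "ec_level": manifest_row.get("ec_level", np.nan),
        "replicate": manifest_row.get("replicate", np.nan),
        **{f"ppm_{k}": v for k, v in ppm.items()},
        "lambda": lam,
        "effective_dose": dose,
        "inhibition_f": f,
        "tau_decline_eff": tau_dec,
        "tau_up_eff": tau_up,
        "stress_on": int(stress_on),
        "recovery_on": int(recovery_on),
        "recovery_amp_eff": rec_amp,
        "i0_true": i0,
        "clean_delta_i_rel": float((post_clean.max() - post_clean.min()) / i0),
    }
    trace = CurrentTrace(
        sample_id=str(manifest_row.get("sample_id", "")),
        times=times,
        currents=currents,
        injection_time=t_inj,
        metadata={
            "setup_id": setup_id,
            "ec_level": manifest_row.get("ec_level"),
            "replicate": manifest_row.get("replicate"),
        },
    )
    return trace, truth


def simulate_dataset(
    manifest: pd.DataFrame,
    params: SimulationParams,
    seed: int = 42,
) -> tuple[list[CurrentTrace], pd.DataFrame]:
    """One trace per manifest row; per-row seeds derived from (seed, row index)."""
    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    traces: list[CurrentTrace] = []
    truths: list[dict] = []
    for idx, (_, row) in enumerate(manifest.iterrows()):
        trace, truth = simulate_trace(row, params, seed=(seed, idx))
        traces.append(trace)
        truths.append(truth)
    return traces, pd.DataFrame(truths)


# -- long-format I/O --------------------------------------------------------

def traces_to_frame(traces: Sequence[CurrentTrace]) -> pd.DataFrame:
    """Long-format (sample_id, time_s, current_mA) table for CSV export."""
    parts = [
        pd.DataFrame({
            "sample_id": t.sample_id,
            "time_s": t.times,
            "current_mA": t.currents,
        })
        for t in traces
    ]
    return pd.concat(parts, ignore_index=True)


def frame_to_traces(
    frame: pd.DataFrame,
    injection_time: float = 60.0,
    metadata: pd.DataFrame | None = None,
) -> list[CurrentTrace]:
    """Rebuild traces from a long-format table (inverse of traces_to_frame)."""
    meta_by_id: dict[str, dict] = {}
    if metadata is not None:
        meta_by_id = metadata.set_index("sample_id").to_dict("index")
    traces = []
    for sample_id, grp in frame.groupby("sample_id", sort=False):
        grp = grp.sort_values("time_s")
        traces.append(CurrentTrace(
            sample_id=str(sample_id),
            times=grp["time_s"].to_numpy(),
            currents=grp["current_mA"].to_numpy(),
            injection_time=injection_time,
            metadata=dict(meta_by_id.get(sample_id, {})),
        ))
    return traces
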