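"""Trace generator: dose arithmetic, curve shape, determinism, invariants."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import mectox as mx
from mectox.design import DEFAULT_PANEL
from mectox.synth import (CurrentTrace, SimulationParams, effective_dose,
                          frame_to_traces, simulate_dataset, simulate_trace,
                          traces_to_frame)


def manifest_row(**ppm):
    row = {"sample_id": "t1", "setup_id": ppm.pop("setup_id", ""),
           "ec_level": 10, "replicate": 1}
    for t in DEFAULT_PANEL:
        row[f"ppm_{t.name}"] = ppm.get(t.name, 0.0)
    return row


class TestEffectiveDose:
    def test_zero_ppm_gives_zero(self):
        assert effective_dose({t.name: 0.0 for t in DEFAULT_PANEL}) == 0.0

    def test_single_at_cmax_gives_ten(self):
        assert effective_dose({"formaldehyde": 200.0}) == pytest.approx(10.0)

    def test_quaternary_equal_ratio_with_antagonism(self):
        # 1:1:1:1 at EC 10: each component at c_max/4, toxic units sum to 1
        ppm = {"formaldehyde": 50.0, "tetracycline": 1.25,
               "silver_nitrate": 25.0, "copper_sulfate": 25.0}
        assert effective_dose(ppm, lam=0.18) == pytest.approx(1.8)

    def test_unknown_toxicant_rejected(self):
        with pytest.raises(KeyError):
            effective_dose({"arsenic": 1.0})

    def test_negative_ppm_rejected(self):
        with pytest.raises(ValueError):
            effective_dose({"formaldehyde": -1.0})


class TestSimulateTrace:
    def test_zero_dose_no_noise_constant(self):
        par = SimulationParams.additive_reference()
        trace, truth = simulate_trace(manifest_row(), par, seed=3)
        assert np.allclose(trace.currents, trace.currents[0])
        assert truth["clean_delta_i_rel"] == pytest.approx(0.0, abs=1e-12)

    def test_inhibition_plateau_closed_form(self):
        # beta=0.02, dose=5 -> f=0.10; short tau so the plateau is reached
        par = SimulationParams.additive_reference(tau_decline=20.0)
        row = manifest_row(formaldehyde=100.0)  # 5 toxic-unit EC
        trace, truth = simulate_trace(row, par, seed=0)
        assert truth["inhibition_f"] == pytest.approx(0.10)
        t_rel, y = trace.post_injection()
        delta_i_rel = (y.max() - y.min()) / truth["i0_true"]
        assert delta_i_rel == pytest.approx(0.10, abs=1e-6)

    def test_seed_determinism_bit_identical(self):
        par = SimulationParams()
        row = manifest_row(formaldehyde=100.0, copper_sulfate=30.0)
        t1, _ = simulate_trace(row, par, seed=99)
        t2, _ = simulate_trace(row, par, seed=99)
        np.testing.assert_array_equal(t1.currents, t2.currents)

    def test_different_seeds_differ(self):
        par = SimulationParams()
        row = manifest_row(formaldehyde=100.0)
        t1, _ = simulate_trace(row, par, seed=1)
        t2, _ = simulate_trace(row, par, seed=2)
        assert not np.array_equal(t1.currents, t2.currents)

    def test_grid_shape_default(self):
        # 60 s baseline + 300 s exposure at 12 s: 5 + 26 samples
        par = SimulationParams()
        trace, _ = simulate_trace(manifest_row(formaldehyde=10.0), par, seed=0)
        assert trace.times.size == 31
        assert trace.step == 12.0
        assert trace.injection_time == 60.0
        t_rel, y = trace.post_injection()
        assert t_rel.size == 26

    def test_stress_raises_predecline_maximum(self):
        par = SimulationParams(noise_sd=0.0, i0_sd=0.0)
        row = manifest_row(formaldehyde=200.0, setup_id="formaldehyde@1")
        trace, truth = simulate_trace(row, par, seed=4)
        assert truth["stress_on"] == 1
        _, y = trace.post_injection()
        assert y.max() > truth["i0_true"]

    def test_recovery_raises_trailing_current(self):
        par = SimulationParams(noise_sd=0.0, i0_sd=0.0)
        # dose 2 EC units: below the recovery threshold of 5
        row = manifest_row(formaldehyde=40.0)
        trace, truth = simulate_trace(row, par, seed=4)
        assert truth["recovery_on"] == 1
        _, y = trace.post_injection()
        imin_idx = int(np.argmin(y))
        assert imin_idx < y.size - 1
        assert y[imin_idx + 1:].max() > y[imin_idx]

    def test_currents_positive(self):
        par = SimulationParams()
        for seed in range(5):
            trace, _ = simulate_trace(
                manifest_row(formaldehyde=200.0), par, seed=seed)
            assert (trace.currents > 0).all()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimulationParams(f_cap=1.0)
        with pytest.raises(ValueError):
            SimulationParams(noise_sd=-0.1)
        with pytest.raises(ValueError):
            SimulationParams(tau_decline=0.0)
        with pytest.raises(ValueError):
            SimulationParams(lambda_map={"a": -1.0})


class TestSimulateDataset:
    def test_one_trace_per_row(self, study):
        assert len(study.traces) == len(study.manifest) == 1290
        assert len(study.truth) == 1290

    def test_empty_manifest_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            simulate_dataset(pd.DataFrame(), SimulationParams(), seed=0)

    def test_noise_free_response_monotone_in_ec(self):
        setups = mx.enumerate_setups()
        manifest = mx.expand_manifest(setups, n_replicates=1)
        par = SimulationParams(noise_sd=0.0, i0_sd=0.0)
        _, truth = simulate_dataset(manifest, par, seed=5)
        for _, grp in truth.groupby("setup_id"):
            resp = grp.sort_values("ec_level")["clean_delta_i_rel"].to_numpy()
            assert (np.diff(resp) >= -1e-12).all()

    def test_dataset_determinism(self):
        setups = mx.enumerate_setups()
        manifest = mx.expand_manifest(setups, n_replicates=1).head(20)
        par = SimulationParams()
        tr1, _ = simulate_dataset(manifest, par, seed=7)
        tr2, _ = simulate_dataset(manifest, par, seed=7)
        for a, b in zip(tr1, tr2):
            np.testing.assert_array_equal(a.currents, b.currents)


class TestTraceIO:
    def test_long_format_roundtrip(self):
        par = SimulationParams()
        traces = [simulate_trace(manifest_row(formaldehyde=50.0), par, s)[0]
                  for s in range(3)]
        for i, t in enumerate(traces):
            t.sample_id = f"s{i}"
        frame = traces_to_frame(traces)
        assert set(frame.columns) == {"sample_id", "time_s", "current_mA"}
        back = frame_to_traces(frame, injection_time=60.0)
        assert len(back) == 3
        for a, b in zip(traces, back):
            np.testing.assert_array_equal(a.currents, b.currents)
            np.testing.assert_array_equal(a.times, b.times)

    def test_trace_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            CurrentTrace("x", [0, 12, 12], [1, 1, 1], 0.0)
        with pytest.raises(ValueError, match="uniform"):
            CurrentTrace("x", [0, 12, 30], [1, 1, 1], 0.0)
        with pytest.raises(ValueError, match="positive"):
            CurrentTrace("x", [0, 12, 24], [1, -1, 1], 0.0)
        with pytest.raises(ValueError, match="post-injection"):
            CurrentTrace("x", [0, 12, 24, 36], [1, 1, 1, 1], 30.0)
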