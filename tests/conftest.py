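"""Shared fixtures: the default study dataset is built once per session."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

import mectox as mx


@dataclass
class StudyData:
    config: mx.RunConfig
    manifest: pd.DataFrame
    params: mx.SimulationParams
    traces: list
    truth: pd.DataFrame
    features: pd.DataFrame
    X: np.ndarray
    Y: pd.DataFrame
    feature_names: list
    groups: np.ndarray


@pytest.fixture(scope="session")
def study() -> StudyData:
    """The default study conditions: 43 setups x 5 ECs x 6 replicates."""
    config = mx.RunConfig()
    manifest, params, traces, truth = mx.build_dataset(config)
    features = mx.featurize_dataset(traces)
    X = features.drop(columns="sample_id").to_numpy()
    th = truth.set_index("sample_id").loc[features["sample_id"]]
    Y = th[[c for c in th.columns if c.startswith("ppm_")]]
    names = [c for c in features.columns if c != "sample_id"]
    groups = (manifest.set_index("sample_id")
              .loc[features["sample_id"], ["setup_id", "ec_level"]]
              .astype(str).agg("|".join, axis=1).to_numpy())
    return StudyData(config, manifest, params, traces, truth, features,
                     X, Y, names, groups)


@pytest.fixture(scope="session")
def rf_results(study: StudyData) -> mx.ConcentrationResults:
    """Cross-validated random-forest fit on the default dataset."""
    model = mx.ConcentrationModel(
        study.X, study.Y, spec=mx.ModelSpec("rf"),
        feature_names=study.feature_names, groups=study.groups)
    return model.fit()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
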