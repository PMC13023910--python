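"""End-to-end orchestration: design → simulate → featurize → metrics → models → validation.

Every stage writes plain CSV/JSON artifacts and consumes only files (or
in-memory tables) produced by earlier stages; a single master seed fans
out to per-stage seeds by fixed offsets so each stage is independently
reproducible.  Identical config + seed reproduces every artifact
bit-for-bit (verified via the SHA-256 manifest written alongside).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import design, metrics, synth
from .features import featurize_dataset
from .models import default_specs
from .regression import ConcentrationModel
from .validation import validation_report

__all__ = ["RunConfig", "run_all", "build_dataset"]

# seed offsets per stage (master seed + offset)
SEED_LAMBDA = 101
SEED_SYNTH = 202


@dataclass
class RunConfig:
    """Declarative description of one full pipeline run."""

    panel: Mapping[str, float] = field(default_factory=lambda: {
        t.name: t.c_max for t in design.DEFAULT_PANEL})
    ec_levels: Sequence[int] = tuple(design.DEFAULT_EC_LEVELS)
    n_replicates: int = 6
    sim: Mapping = field(default_factory=dict)   # SimulationParams overrides
    lambda_low: float = 0.25
    lambda_high: float = 1.8
    pin_lambdas: bool = True
    smooth_window: int = 5
    kappa: float = 3.0
    baseline_window_s: float = 60.0
    model_seed: int = 42
    cv_folds: int = 10
    models: Sequence[str] = ("svm", "knn", "pls", "rf")
    run_validation: bool = True
    learning_sizes: Sequence[int] | None = None
    seed: int = 42

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ec_levels"] = list(d["ec_levels"])
        d["models"] = list(d["models"])
        if d["learning_sizes"] is not None:
            d["learning_sizes"] = list(d["learning_sizes"])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    # -- derived objects ----------------------------------------------------

    def panel_toxicants(self) -> tuple[design.Toxicant, ...]:
        return design.panel_from_mapping(self.panel)

    def sim_params(self, lambda_map: Mapping[str, float]) -> synth.SimulationParams:
        return synth.SimulationParams(
            panel=self.panel_toxicants(), lambda_map=dict(lambda_map),
            **dict(self.sim))


def build_dataset(config: RunConfig):
    """Design the manifest, draw interaction factors, simulate all traces.

    Returns (manifest, params, traces, truth).
    """
    panel = config.panel_toxicants()
    setups = design.enumerate_setups(panel)
    manifest = design.expand_manifest(
        setups, panel, ec_levels=config.ec_levels,
        n_replicates=config.n_replicates)
    pinned = None if config.pin_lambdas else {}
    lambda_map = synth.default_lambda_map(
        setups, seed=config.seed + SEED_LAMBDA,
        low=config.lambda_low, high=config.lambda_high, pinned=pinned)
    params = config.sim_params(lambda_map)
    traces, truth = synth.simulate_dataset(
        manifest, params, seed=config.seed + SEED_SYNTH)
    return manifest, params, traces, truth


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_all(config: RunConfig, outdir: str | Path, force: bool = False) -> dict:
    """Run every stage and write all artifacts into ``outdir``.

    Refuses to write into a non-empty directory unless ``force`` is set.
    Returns a summary dict with artifact paths, scores and hashes.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    existing = [p for p in out.iterdir() if p.name != "config.yaml"]
    if existing and not force:
        raise FileExistsError(
            f"{out} is not empty; pass force=True to overwrite")

    config.to_yaml(out / "config.yaml")
    manifest, params, traces, truth = build_dataset(config)
    _write_csv(manifest, out / "manifest.csv")
    _write_csv(synth.traces_to_frame(traces), out / "traces.csv")
    _write_csv(truth, out / "truth.csv")

    features = featurize_dataset(
        traces, smooth_window=config.smooth_window, kappa=config.kappa,
        baseline_window_s=config.baseline_window_s)
    _write_csv(features, out / "features.csv")

    responses = features.set_index("sample_id")["delta_i_rel"]
    ii = metrics.mixture_interaction_table(manifest, responses)
    _write_csv(ii, out / "ii.csv")
    calib = metrics.calibration_table(manifest, traces)
    _write_csv(calib, out / "calibration.csv")

    specs = [s for s in default_specs(seed=config.model_seed,
                                      cv_folds=config.cv_folds)
             if s.kind in set(config.models)]
    truth_cols = ["sample_id"] + [c for c in truth.columns
                                  if c.startswith("ppm_")]
    merged_groups = manifest.set_index("sample_id").loc[
        features["sample_id"], ["setup_id", "ec_level"]]
    X = features.drop(columns="sample_id").to_numpy()
    Y = truth.set_index("sample_id").loc[
        features["sample_id"],
        [c for c in truth.columns if c.startswith("ppm_")]]
    feat_names = [c for c in features.columns if c != "sample_id"]
    groups = merged_groups.astype(str).agg("|".join, axis=1).to_numpy()

    rf_spec = next((s for s in specs if s.kind == "rf"), None)
    score_frames, pred_frames = [], []
    for spec in specs:
        res = ConcentrationModel(X, Y, spec=spec, feature_names=feat_names,
                                 groups=groups).fit()
        sc = res.scores.copy()
        sc.insert(0, "model", spec.kind)
        score_frames.append(sc)
        for tox, (yt, yp) in res.predictions.items():
            pred_frames.append(pd.DataFrame({
                "model": spec.kind, "toxicant": tox,
                "sample_id": features["sample_id"], "y_true": yt, "y_pred": yp}))
    scores = pd.concat(score_frames, ignore_index=True)
    _write_csv(scores, out / "scores.csv")
    _write_csv(pd.concat(pred_frames, ignore_index=True),
               out / "predictions.csv")

    report = None
    if config.run_validation and rf_spec is not None:
        report = validation_report(
            X, Y, feat_names, groups=groups, spec=rf_spec,
            seed=config.model_seed, sizes=config.learning_sizes)
        with open(out / "validation_report.json", "w") as fh:
            json.dump(report, fh, indent=1)

    artifacts = sorted(p for p in out.iterdir() if p.is_file())
    hashes = {p.name: _sha256(p) for p in artifacts if p.name != "hashes.json"}
    with open(out / "hashes.json", "w") as fh:
        json.dump(hashes, fh, indent=1)

    return {
        "outdir": str(out),
        "n_samples": len(manifest),
        "scores": scores,
        "interaction": ii,
        "validation": report,
        "hashes": hashes,
    }
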