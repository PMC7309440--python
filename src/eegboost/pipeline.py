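"""End-to-end pipeline: simulate (or load) a cohort, extract spectral
features, run the per-symptom model search in each input mode, evaluate
discrimination/calibration, compare EEG+HRSD against HRSD-only, attribute
feature importance, and write a reproducible run directory.

Every run is driven by a structured YAML config with a mandatory global
seed; identical config + seed produces byte-identical JSON/CSV outputs (no
timestamps enter any report).  A manifest records package version, seeds,
and SHA-256 hashes of every artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import apply_exclusions, read_scores
from .evaluate import EvalConfig, calibrate, delta_c_index, fit_metrics
from .report import (
    bucket_edges_from_predictions,
    c_index_table,
    delta_c_table,
    explain_patient,
    importance_table,
)
from .search import (
    AnalysisDataset,
    CVConfig,
    ModelResult,
    SearchSpace,
    TreeParams,
    build_features,
    enumerate_feature_combinations,
    fit_gbdt,
    search,
)
from .shapley import aggregate_importance
from .simulate import EffectSpec, SimulationConfig, simulate_cohort, write_cohort
from .spectral import EEGRecording, cohort_band_powers

log = logging.getLogger("eegboost")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


@dataclass
class RunConfig:
    seed: int
    output_dir: Path
    symptoms: tuple[int, ...] = tuple(range(1, 22))
    modes: tuple[str, ...] = ("eeg+hrsd", "hrsd")
    with_treatment: bool = False
    space: SearchSpace = field(default_factory=SearchSpace)
    grid: tuple[TreeParams, ...] = (TreeParams(),)
    cv: CVConfig = field(default_factory=CVConfig)
    eval_cfg: EvalConfig = field(default_factory=EvalConfig)
    simulation: Optional[SimulationConfig] = None
    scores_path: Optional[Path] = None
    eeg_dir: Optional[Path] = None
    bucket_edges: Optional[tuple[float, float, float]] = None
    min_child_samples: Optional[int] = None
    nested: bool = False

    def __post_init__(self) -> None:
        if self.simulation is None and self.scores_path is None:
            raise PipelineError("[config] neither a simulation block nor a scores path given")
        if self.scores_path is not None and not Path(self.scores_path).exists():
            raise PipelineError(f"[config] scores path {self.scores_path} does not exist")


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file (see docs for the schema)."""
    raw = yaml.safe_load(Path(path).read_text())
    if "seed" not in raw:
        raise PipelineError("[config] a global seed is mandatory")
    seed = int(raw["seed"])

    sim = None
    if "simulation" in raw:
        s = dict(raw["simulation"])
        effects = tuple(EffectSpec(**e) for e in s.pop("effects", []))
        s.setdefault("seed", seed)
        sim = SimulationConfig(effects=effects, **s)

    space_kwargs = {}
    for key, value in raw.get("search_space", {}).items():
        if key == "extras":
            space_kwargs[key] = tuple((bool(a), bool(b)) for a, b in value)
        else:
            space_kwargs[key] = tuple(value)
    space = SearchSpace(**space_kwargs)
    grid = tuple(
        TreeParams(**{**g, "seed": int(g.get("seed", seed))}) for g in raw.get("grid", [])
    ) or (TreeParams(seed=seed),)
    cv = CVConfig(**{**raw.get("cv", {}), "seed": int(raw.get("cv", {}).get("seed", seed))})
    ev = EvalConfig(**{**raw.get("eval", {}), "seed": int(raw.get("eval", {}).get("seed", seed))})

    return RunConfig(
        seed=seed,
        output_dir=Path(raw.get("output_dir", "runs/run")),
        symptoms=tuple(raw.get("symptoms", range(1, 22))),
        modes=tuple(raw.get("modes", ("eeg+hrsd", "hrsd"))),
        with_treatment=bool(raw.get("with_treatment", False)),
        space=space,
        grid=grid,
        cv=cv,
        eval_cfg=ev,
        simulation=sim,
        scores_path=Path(raw["scores_path"]) if "scores_path" in raw else None,
        eeg_dir=Path(raw["eeg_dir"]) if "eeg_dir" in raw else None,
        bucket_edges=tuple(raw["bucket_edges"]) if "bucket_edges" in raw else None,
        min_child_samples=raw.get("min_child_samples"),
        nested=bool(raw.get("nested", False)),
    )


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # tag and re-raise
                raise PipelineError(f"[{name}] {exc}") from exc
            log.info("stage %s: done", name)
            return out
        return wrapped
    return deco


@_stage("data")
def _acquire_data(config: RunConfig):
    """Simulate or load the cohort and its band powers."""
    if config.simulation is not None:
        sim = simulate_cohort(config.simulation)
        cohort = apply_exclusions(sim.cohort.subjects)
        if sim.recordings is not None:
            band_powers = cohort_band_powers(sim.recordings)
        else:
            band_powers = sim.band_powers
        return cohort, band_powers, sim
    subjects = read_scores(config.scores_path)
    cohort = apply_exclusions(subjects)
    if config.eeg_dir is None:
        raise PipelineError("[data] scores without an eeg_dir of recordings")
    recordings = {}
    for sid in cohort.subject_ids:
        f_csv = Path(config.eeg_dir) / f"{sid}.csv"
        f_edf = Path(config.eeg_dir) / f"{sid}.edf"
        if f_csv.exists():
            recordings[sid] = EEGRecording.from_csv(f_csv)
        elif f_edf.exists():
            recordings[sid] = EEGRecording.from_edf(f_edf)
        else:
            raise PipelineError(f"[data] no EEG file for subject {sid}")
    return cohort, cohort_band_powers(recordings), None


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "results").mkdir(exist_ok=True)

    cohort, band_powers, sim = _acquire_data(config)
    if len(cohort) == 0:
        raise PipelineError("[data] no subjects survive the exclusion flow")
    dataset = AnalysisDataset.from_cohort(cohort, band_powers)

    if sim is not None:
        write_cohort(sim, out / "input")
    cohort.write_provenance(out / "results" / "provenance.json")
    flat = band_powers.copy()
    flat.columns = [f"{s}|{b}" for s, b in flat.columns]
    flat.loc[cohort.subject_ids].rename_axis("subject_id").to_csv(out / "results" / "band_powers.csv")

    combos = enumerate_feature_combinations(config.space)
    results: dict[str, dict[int, ModelResult]] = {m: {} for m in config.modes}
    importances: dict[int, dict] = {}
    explanations: list[dict] = []

    for symptom in config.symptoms:
        for mode in config.modes:
            res = _run_one(config, dataset, symptom, mode, combos)
            results[mode][symptom] = res
            _json_dump(res.to_dict(), out / "results" / f"symptom_{symptom:02d}_{mode.replace('+', '_')}.json")
            res.predictions.rename("prediction").rename_axis("subject_id").to_csv(
                out / "results" / f"predictions_{symptom:02d}_{mode.replace('+', '_')}.csv"
            )
        primary = results[config.modes[0]][symptom]
        imp = _importance_for(config, dataset, primary)
        importances[symptom] = {
            "symptom": symptom,
            "top3": imp.top(3),
            "percents": imp.to_dict(),
        }
        _json_dump(importances[symptom], out / "results" / f"importance_{symptom:02d}.json")
        explanations.append(_explain_first_subject(config, dataset, primary).to_dict())

    cal = _calibration_metrics(config, dataset, results)
    _json_dump(cal, out / "results" / "calibration.json")

    deltas = {}
    if "eeg+hrsd" in config.modes and "hrsd" in config.modes:
        for symptom in config.symptoms:
            a = results["eeg+hrsd"][symptom].predictions.to_numpy()
            b = results["hrsd"][symptom].predictions.to_numpy()
            deltas[symptom] = delta_c_index(a, b, dataset.outcome(symptom), config.eval_cfg)
        _json_dump(
            {
                str(s): {"delta_c": d.delta_c, "ci_low": d.ci_low, "ci_high": d.ci_high,
                         "significant": d.significant}
                for s, d in deltas.items()
            },
            out / "results" / "delta_c.json",
        )
    _json_dump(explanations, out / "results" / "explanations.json")

    _write_summary(out, config, cohort, results, deltas, importances)
    _write_manifest(out, config)
    return out


@_stage("search")
def _run_one(config, dataset, symptom, mode, combos) -> ModelResult:
    return search(
        dataset,
        symptom,
        combos,
        config.grid,
        cv=config.cv,
        input_mode=mode,
        with_treatment=config.with_treatment,
        eval_cfg=config.eval_cfg,
        min_child_samples=config.min_child_samples,
        nested=config.nested,
    )


@_stage("importance")
def _importance_for(config, dataset, result: ModelResult):
    """Shapley attributions from the fold-specific models applied to their
    validation folds, pooled — mirroring the pooled-prediction philosophy."""
    from .search import pooled_cv_attributions

    attr = pooled_cv_attributions(
        dataset, result, cv=config.cv, min_child_samples=config.min_child_samples
    )
    return aggregate_importance(attr)


@_stage("explain")
def _explain_first_subject(config, dataset, result: ModelResult):
    features = build_features(
        dataset, result.combination, result.input_mode, result.with_treatment
    )
    model = fit_gbdt(features, dataset.outcome(result.symptom), result.params)
    edges = config.bucket_edges or bucket_edges_from_predictions(result.predictions.to_numpy())
    return explain_patient(model, features.iloc[0], edges, symptom=result.symptom)


@_stage("evaluate")
def _calibration_metrics(config, dataset, results) -> dict:
    """Calibration (lasso, coefficient 0.01) and goodness of fit per model,
    computed between training-mode outputs and the observed improvements."""
    out = {}
    for mode, by_symptom in results.items():
        for symptom, res in by_symptom.items():
            y = dataset.outcome(symptom)
            features = build_features(dataset, res.combination, res.input_mode, res.with_treatment)
            model = fit_gbdt(features, y, res.params)
            train_out = model.predict(features)
            calib = calibrate(train_out, y, lam=0.01)
            fm = fit_metrics(calib, res.predictions.to_numpy(), y)
            out[f"{symptom:02d}_{mode}"] = {
                "r_squared": fm.r_squared,
                "mae": fm.mean_absolute_error,
                "slope": fm.slope,
                "intercept": fm.intercept,
            }
    return out


def _write_summary(out, config, cohort, results, deltas, importances) -> None:
    lines = ["# Run summary", ""]
    lines.append(f"- subjects after exclusions: {len(cohort)}")
    lines.append(f"- seed: {config.seed}")
    lines.append("")
    for mode, by_symptom in results.items():
        lines.append(f"## Discrimination ({mode})")
        lines.append("")
        lines.append(c_index_table(list(by_symptom.values())).to_markdown(index=False))
        lines.append("")
    if deltas:
        lines.append("## EEG+HRSD vs HRSD-only")
        lines.append("")
        lines.append(delta_c_table(deltas).to_markdown(index=False))
        lines.append("")
    lines.append("## Top features (mean |Shapley| % of total)")
    lines.append("")
    for symptom, imp in importances.items():
        lines.append(f"### Item {symptom}")
        lines.append("")
        top = pd.Series({k: v for k, v in dict(imp["percents"]).items()})
        lines.append(importance_table(top.head(3)).to_markdown(index=False))
        lines.append("")
    (out / "summary.md").write_text("\n".join(lines))


def _write_manifest(out: Path, config: RunConfig) -> None:
    files = sorted(
        p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "package": "eegboost",
        "version": __version__,
        "seed": config.seed,
        "hashes": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    _json_dump(manifest, out / "manifest.json")
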