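"""End-to-end pipeline orchestration: simulate (or load) -> connectivity ->
train -> interpret -> evaluate, from a single validated config.

Every random draw derives from the master seed through a
``numpy.random.SeedSequence`` spawn tree (one child per stage, in a fixed
order), so a run is reproducible from its manifest alone: re-running with the
same config and seed byte-matches every CSV/JSON artifact, which the manifest
records with SHA-256 checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from ._exceptions import SpecValidationError, StageError
from . import __version__ as _version
from .classifier import TrainConfig, run_experiment
from .connectivity import (
    ConnectivityDataset,
    build_connectivity_dataset,
    correlation_matrix,
    preprocess_series,
    select_cois,
)
from .evaluation import (
    evaluate_experiment,
    modal_participant_accuracy,
    write_metrics_json,
)
from .interpretation import (
    normalize_path_weights,
    predictive_connection_table,
    reduced_feature_selection,
    summed_path_weights,
    targeted_vs_random_test,
)
from .synthetic import CohortSpec, generate_cohort, read_cohort_csv, write_cohort_csv

log = logging.getLogger("xmiconnect")

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "read_write_roundtrip"]


@dataclass(frozen=True)
class ConnectivityConfig:
    clip_z: float = 3.0
    top_frac: float = 0.05
    min_prop: float = 0.30
    absolute: bool = False
    bandwidth: float = 1.0

    def __post_init__(self) -> None:
        if self.clip_z <= 0:
            raise SpecValidationError("clip_z must be positive")
        if not (0 < self.top_frac <= 1):
            raise SpecValidationError("top_frac must lie in (0, 1]")
        if not (0 <= self.min_prop <= 1):
            raise SpecValidationError("min_prop must lie in [0, 1]")
        if self.bandwidth < 0:
            raise SpecValidationError("bandwidth must be >= 0")


@dataclass(frozen=True)
class InterpretationConfig:
    tail: float = 0.025
    z_thresh: float = 1.65
    comparison_sets: int = 10
    comparison_folds: int = 10
    run_comparison: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.tail < 0.5):
            raise SpecValidationError("tail must lie in (0, 0.5)")
        if self.z_thresh <= 0:
            raise SpecValidationError("z_thresh must be positive")


@dataclass(frozen=True)
class PipelineConfig:
    """Full pipeline configuration.  Either a synthetic cohort spec or an
    input directory of time-series CSVs (with labels.csv) must be given."""

    cohort: CohortSpec | None = None
    input_dir: str | None = None
    connectivity: ConnectivityConfig = field(default_factory=ConnectivityConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    interpretation: InterpretationConfig = field(default_factory=InterpretationConfig)
    n_batches: int = 6
    k_folds: int = 5
    seed: int = 0
    write_series: bool = False

    def __post_init__(self) -> None:
        if (self.cohort is None) == (self.input_dir is None):
            raise SpecValidationError(
                "exactly one of cohort spec or input_dir must be provided"
            )
        if self.n_batches < 1 or self.k_folds < 2:
            raise SpecValidationError("n_batches >= 1 and k_folds >= 2 required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        kwargs: dict[str, Any] = {}
        if "cohort" in raw and raw["cohort"] is not None:
            cohort = dict(raw["cohort"])
            for key in ("planted_clinical_pairs", "planted_igt_pairs"):
                if key in cohort:
                    cohort[key] = tuple(tuple(p) for p in cohort[key])
            for key in ("clinical_directions", "igt_directions"):
                if key in cohort and cohort[key] is not None:
                    cohort[key] = tuple(cohort[key])
            kwargs["cohort"] = CohortSpec(**cohort)
        if raw.get("input_dir"):
            kwargs["input_dir"] = str(raw["input_dir"])
        if "connectivity" in raw:
            kwargs["connectivity"] = ConnectivityConfig(**raw["connectivity"])
        if "training" in raw:
            kwargs["training"] = TrainConfig(**raw["training"])
        if "interpretation" in raw:
            kwargs["interpretation"] = InterpretationConfig(**raw["interpretation"])
        for key in ("n_batches", "k_folds", "seed", "write_series"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def to_dict(self) -> dict[str, Any]:
        out = asdict(self)
        return out


@dataclass
class RunManifest:
    """Record of a pipeline run: config snapshot, derived seeds, software
    version, and per-artifact paths with SHA-256 checksums."""

    config: dict[str, Any]
    version: str
    master_seed: int
    stage_seeds: dict[str, int]
    artifacts: dict[str, str]
    checksums: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seeds(master: int) -> dict[str, int]:
    names = ("simulate", "train", "interpret", "evaluate")
    children = np.random.SeedSequence(master).spawn(len(names))
    return {
        name: int(ss.generate_state(1)[0] % (2**31))
        for name, ss in zip(names, children)
    }


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Execute the full analysis and write all artifacts plus a manifest.

    Stages: simulate (or load) -> connectivity -> train -> interpret ->
    evaluate.  Any stage failure aborts with a :class:`StageError` naming
    the stage and the cause.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    artifacts: dict[str, str] = {}

    def _record(name: str, path: Path) -> None:
        artifacts[name] = str(path)

    # -- simulate / load --------------------------------------------------
    try:
        if config.cohort is not None:
            spec = dataclasses.replace(config.cohort, seed=seeds["simulate"])
            log.info("simulate: %d participants x %d runs, %d ROIs",
                     spec.n_participants, spec.n_runs, spec.n_rois)
            series, labels, truth = generate_cohort(spec)
            truth_path = out / "ground_truth.json"
            truth.to_json(truth_path)
            _record("ground_truth", truth_path)
            if config.write_series:
                write_cohort_csv(series, labels, truth, out)
        else:
            log.info("load: %s", config.input_dir)
            series, labels = read_cohort_csv(config.input_dir)
        labels_path = out / "labels.csv"
        labels.to_csv(labels_path, index=False)
        _record("labels", labels_path)
    except Exception as exc:  # noqa: BLE001 - rewrapped with stage context
        raise StageError("simulate", exc) from exc

    # -- connectivity ------------------------------------------------------
    try:
        cc = config.connectivity
        log.info("connectivity: clip_z=%g top_frac=%g min_prop=%g bandwidth=%g",
                 cc.clip_z, cc.top_frac, cc.min_prop, cc.bandwidth)
        clean = [preprocess_series(ts, clip_z=cc.clip_z) for ts in series]
        matrices = [correlation_matrix(ts) for ts in clean]
        cois = select_cois(
            matrices, top_frac=cc.top_frac, min_prop=cc.min_prop, absolute=cc.absolute
        )
        dataset = build_connectivity_dataset(
            clean, cois, labels, bandwidth=cc.bandwidth, preprocessed=True
        )
        dataset_path = out / "dataset.csv"
        dataset.to_csv(dataset_path)
        _record("dataset", dataset_path)
    except Exception as exc:  # noqa: BLE001
        raise StageError("connectivity", exc) from exc

    # -- train -------------------------------------------------------------
    try:
        log.info("train: %d batches x %d folds", config.n_batches, config.k_folds)
        result = run_experiment(
            dataset,
            n_batches=config.n_batches,
            k=config.k_folds,
            config=config.training,
            seed=seeds["train"],
        )
        models_dir = out / "models"
        models_dir.mkdir(exist_ok=True)
        for i, model in enumerate(result.models):
            model.to_json(models_dir / f"model_{i:03d}.json")
        preds_path = out / "predictions.csv"
        result.predictions.to_csv(preds_path, index=False)
        _record("predictions", preds_path)
        acc_path = out / "model_accuracies.csv"
        result.accuracy_summary().to_csv(acc_path, index=False)
        _record("model_accuracies", acc_path)
    except Exception as exc:  # noqa: BLE001
        raise StageError("train", exc) from exc

    # -- interpret ---------------------------------------------------------
    try:
        ic = config.interpretation
        weight_table = normalize_path_weights(
            [summed_path_weights(m) for m in result.models],
            feature_names=dataset.feature_names,
        )
        weights_path = out / "path_weights.csv"
        weight_table.to_csv(weights_path, index=False)
        _record("path_weights", weights_path)
        pred_table = predictive_connection_table(weight_table, z_thresh=ic.z_thresh)
        table_path = out / "predictive_connections.csv"
        pred_table.to_csv(table_path, index=False)
        _record("predictive_connections", table_path)
        reduced = reduced_feature_selection(weight_table, tail=ic.tail)
        reduced_path = out / "reduced_features.json"
        reduced_path.write_text(json.dumps(
            {"indices": reduced, "features": [dataset.feature_names[i] for i in reduced]}
        ))
        _record("reduced_features", reduced_path)
        if ic.run_comparison:
            pool = [i for i in range(len(dataset.pairs)) if i not in set(reduced)]
            if reduced and len(pool) >= len(reduced):
                report = targeted_vs_random_test(
                    dataset,
                    targeted_features=reduced,
                    pool_features=pool,
                    n_sets=ic.comparison_sets,
                    k=ic.comparison_folds,
                    config=config.training,
                    seed=seeds["interpret"],
                )
                cmp_path = out / "comparison.json"
                report.to_json(cmp_path)
                _record("comparison", cmp_path)
            else:
                log.warning("interpret: skipping comparison (pool smaller than targeted set)")
    except Exception as exc:  # noqa: BLE001
        raise StageError("interpret", exc) from exc

    # -- evaluate ----------------------------------------------------------
    try:
        reports = evaluate_experiment(result)
        metrics = {k: v.to_dict() for k, v in reports.items()}
        metrics["modal_participant_accuracy"] = {
            out_name: modal_participant_accuracy(result.predictions, out_name)
            for out_name in result.outputs
        }
        metrics_path = out / "metrics.json"
        metrics_path.write_text(json.dumps(metrics, indent=2))
        _record("metrics", metrics_path)
    except Exception as exc:  # noqa: BLE001
        raise StageError("evaluate", exc) from exc

    checksums = {name: _sha256(Path(p)) for name, p in artifacts.items()}
    manifest = RunManifest(
        config=config.to_dict(),
        version=_version,
        master_seed=config.seed,
        stage_seeds=seeds,
        artifacts=artifacts,
        checksums=checksums,
    )
    manifest.to_json(out / "manifest.json")
    return manifest


def read_write_roundtrip(path: str | Path) -> ConnectivityDataset:
    """Read a connectivity dataset CSV (the package's dialect) with validation."""
    return ConnectivityDataset.from_csv(path)
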