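"""End-to-end orchestration: simulate -> metrics -> compare -> turing.

One :class:`RunConfig` (a YAML/JSON document validated by
:func:`validate_config`) drives the whole evaluation; every stage writes a
plain CSV so each intermediate is independently inspectable, and all
randomness flows from ``master_seed`` so a rerun is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .cohort_stats import compare_cohorts, comparisons_to_frame
from .preprocessing import load_image
from .synthetic import (
    SynthConfig,
    default_reader_panel,
    derive_seed,
    generate_cohorts,
    simulate_reader_responses,
)
from .turing import cluster_bootstrap_contrast, group_summary
from .vessel_metrics import DiscGeometry, MetricConfig, compute_image_metrics

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "RunRecord",
    "ConfigValidationError",
    "DependencyError",
    "validate_config",
    "run_pipeline",
    "compute_manifest_metrics",
]

STAGES = ("simulate", "metrics", "compare", "turing")


class ConfigValidationError(ValueError):
    """One or more problems in a run-config document (all listed at once)."""


class DependencyError(RuntimeError):
    """A stage's upstream artifact is missing."""


@dataclass
class StatsParams:
    welch: bool = False
    alpha: float = 0.05
    image_size: int | None = None  # default: the cohort frame size


@dataclass
class TuringParams:
    n_images: int = 100
    n_residents: int = 12
    n_non_retina: int = 14
    n_retina: int = 14
    latent_sensitivity: float = 0.711
    latent_specificity: float = 0.369
    reader_effect_sd: float = 0.9
    image_effect_sd: float = 0.5
    grouping: str = "specialty"
    reference_group: str = "resident"
    n_boot: int = 1000


@dataclass
class RunConfig:
    master_seed: int = 0
    workdir: str = "fundus_eval_run"
    n_per_cohort: int = 20
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    cohort_real: SynthConfig = field(default_factory=SynthConfig)
    cohort_synth: SynthConfig = field(default_factory=SynthConfig)
    metrics: MetricConfig = field(default_factory=MetricConfig)
    stats: StatsParams = field(default_factory=StatsParams)
    turing: TuringParams = field(default_factory=TuringParams)


@dataclass
class RunRecord:
    config: dict
    version: str
    stage_rows: dict[str, int]
    stage_seconds: dict[str, float]
    dropped_records: int


def _coerce_dataclass(cls, doc: Any, where: str, problems: list[str]):
    """Build dataclass ``cls`` from a mapping, collecting all problems."""
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        problems.append(f"{where}: expected a mapping, got {type(doc).__name__}")
        return cls()
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in doc.items():
        if key not in fields:
            problems.append(f"{where}: unknown key {key!r}")
            continue
        ftype = fields[key].type
        if dataclasses.is_dataclass(_DATACLASS_FIELDS.get((cls, key), None)):
            value = _coerce_dataclass(
                _DATACLASS_FIELDS[(cls, key)], value, f"{where}.{key}", problems
            )
        elif isinstance(value, list) and key != "stages":
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        problems.append(f"{where}: {exc}")
        return cls()


_DATACLASS_FIELDS = {
    (RunConfig, "cohort_real"): SynthConfig,
    (RunConfig, "cohort_synth"): SynthConfig,
    (RunConfig, "metrics"): MetricConfig,
    (RunConfig, "stats"): StatsParams,
    (RunConfig, "turing"): TuringParams,
}


def validate_config(doc: dict | None) -> RunConfig:
    """Schema-check a raw YAML/JSON document into a RunConfig.

    Unknown keys, type mismatches and invariant breaches are all reported
    together in one :class:`ConfigValidationError`.
    """
    problems: list[str] = []
    cfg = _coerce_dataclass(RunConfig, doc, "config", problems)
    for name in cfg.stages:
        if name not in STAGES:
            problems.append(f"config.stages: unknown stage {name!r}")
    for label, sc in (("cohort_real", cfg.cohort_real),
                      ("cohort_synth", cfg.cohort_synth)):
        try:
            sc.validate()
        except ValueError as exc:
            problems.append(f"config.{label}: {exc}")
    if cfg.n_per_cohort < 1:
        problems.append("config.n_per_cohort: must be >= 1")
    if not (0 < cfg.stats.alpha < 1):
        problems.append("config.stats.alpha: must lie in (0, 1)")
    if problems:
        raise ConfigValidationError("; ".join(problems))
    return cfg


def compute_manifest_metrics(
    manifest: pd.DataFrame, base_dir: str | Path, config: MetricConfig | None = None
) -> pd.DataFrame:
    """Run the vessel metrics over every image of a cohort manifest."""
    base = Path(base_dir)
    rows = []
    for _, row in manifest.iterrows():
        image = load_image(base / row["path_image"], id=str(row["id"]),
                           cohort=str(row["cohort"]))
        mask_img = load_image(base / row["path_mask"])
        mask = mask_img.pixels > 0.5
        disc = DiscGeometry(
            center=(float(row["disc_row"]), float(row["disc_col"])),
            diameter=float(row["disc_diameter"]),
        )
        metrics, _ = compute_image_metrics(image, mask, disc, config)
        rows.append({
            "image_id": row["id"],
            "cohort": row["cohort"],
            "vessel_amount": metrics.vessel_amount,
            "mean_snr": metrics.mean_snr,
            "n_points": metrics.n_points,
            "n_segments": metrics.n_segments,
            "n_dropped": metrics.n_dropped,
        })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> RunRecord:
    """Execute the enabled stages in order, writing each stage's CSV."""
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    stage_rows: dict[str, int] = {}
    stage_seconds: dict[str, float] = {}
    dropped = 0
    manifest_path = workdir / "manifest.csv"
    metrics_path = workdir / "metrics.csv"

    def _stage(name: str) -> bool:
        return name in config.stages

    try:
        if _stage("simulate"):
            t0 = time.perf_counter()
            manifest = generate_cohorts(
                config.cohort_real, config.cohort_synth, config.n_per_cohort,
                workdir, cohort_names=("real", "synthesized"),
                master_seed=derive_seed(config.master_seed, 0),
            )
            stage_rows["simulate"] = len(manifest)
            stage_seconds["simulate"] = time.perf_counter() - t0
            logger.info("simulate: %d images -> %s", len(manifest), workdir)

        if _stage("metrics"):
            if not manifest_path.exists():
                raise DependencyError("stage 'metrics' needs manifest.csv "
                                      "(run the 'simulate' stage first)")
            t0 = time.perf_counter()
            manifest = pd.read_csv(manifest_path)
            metrics = compute_manifest_metrics(manifest, workdir, config.metrics)
            metrics.to_csv(metrics_path, index=False)
            dropped += int(metrics["n_dropped"].sum())
            stage_rows["metrics"] = len(metrics)
            stage_seconds["metrics"] = time.perf_counter() - t0
            logger.info("metrics: %d rows, %d dropped points", len(metrics), dropped)

        if _stage("compare"):
            if not metrics_path.exists():
                raise DependencyError("stage 'compare' needs metrics.csv "
                                      "(run the 'metrics' stage first)")
            t0 = time.perf_counter()
            table = pd.read_csv(metrics_path)
            size = config.stats.image_size or config.cohort_real.image_size
            variant = "welch" if config.stats.welch else "pooled"
            comps = [
                compare_cohorts(table, m, image_size=size, variant=variant)
                for m in ("vessel_amount", "mean_snr")
            ]
            comparisons_to_frame(comps).to_csv(workdir / "comparison.csv", index=False)
            stage_rows["compare"] = len(comps)
            stage_seconds["compare"] = time.perf_counter() - t0

        if _stage("turing"):
            if not manifest_path.exists():
                raise DependencyError("stage 'turing' needs manifest.csv "
                                      "(run the 'simulate' stage first)")
            t0 = time.perf_counter()
            manifest = pd.read_csv(manifest_path)
            tp = config.turing
            half = min(tp.n_images // 2, config.n_per_cohort)
            truths: dict[str, str] = {}
            for cohort, label in (("real", "real"), ("synthesized", "synthesized")):
                ids = manifest.loc[manifest["cohort"] == cohort, "id"][:half]
                truths.update({str(i): label for i in ids})
            panel = default_reader_panel(
                tp.n_residents, tp.n_non_retina, tp.n_retina,
                tp.latent_sensitivity, tp.latent_specificity,
                tp.reader_effect_sd, tp.image_effect_sd,
            )
            responses = simulate_reader_responses(
                panel, truths, seed=derive_seed(config.master_seed, 1)
            )
            responses.to_csv(workdir / "responses.csv", index=False)
            group_summary(responses, tp.grouping).to_csv(
                workdir / "turing_summary.csv", index=False
            )
            contrasts = pd.concat([
                cluster_bootstrap_contrast(
                    responses, tp.grouping, tp.reference_group, metric,
                    n_boot=tp.n_boot, seed=derive_seed(config.master_seed, 2),
                )
                for metric in ("accuracy", "sensitivity", "specificity", "elapsed_s")
            ], ignore_index=True)
            contrasts.to_csv(workdir / "turing_contrasts.csv", index=False)
            stage_rows["turing"] = len(responses)
            stage_seconds["turing"] = time.perf_counter() - t0
    except DependencyError:
        raise
    except Exception as exc:  # label failures with the stage
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    record = RunRecord(
        config=_config_snapshot(config),
        version=__version__,
        stage_rows=stage_rows,
        stage_seconds={k: round(v, 3) for k, v in stage_seconds.items()},
        dropped_records=dropped,
    )
    with open(workdir / "run_record.json", "w") as fh:
        json.dump(dataclasses.asdict(record), fh, indent=2, default=_jsonable)
    return record


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _config_snapshot(config: RunConfig) -> dict:
    snap = dataclasses.asdict(config)

    def clean(x):
        if isinstance(x, dict):
            return {k: clean(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [clean(v) for v in x]
        return x

    return clean(snap)
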