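"""End-to-end orchestration: simulate → preprocess → network → metrics → stats.

Every stage reads its inputs from, and writes its outputs to, plain TSV
tables under the run directory, so any stage can be re-run or resumed from
the previous stage's on-disk outputs. A resolved copy of the configuration
and a machine-readable manifest (timings, record counts, headline results)
are written alongside.

Layout of a run directory::

    config.json              resolved configuration
    run_manifest.json        stage timings, counts, summary
    montage.tsv              channel table
    subjects.tsv             demographics + symptom scores
    series/<sid>_<chrom>.tsv raw simulated recordings
    clean/<sid>_<chrom>.tsv  preprocessed recordings
    artifact_report.tsv      per-subject artifact percentage
    zmat/<sid>_<chrom>.tsv   Fisher-z connectivity matrices
    metrics.tsv              tidy AUC table (global + nodal metrics)
    stats/…                  trajectory fits, partial correlations, t tests
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from .connectivity import correlation_matrix, threshold_by_sparsity
from .graph import compute_subject_metrics
from .montage import make_montage, validate_montage
from .preprocess import PreprocessConfig, clean_series
from .simulate import CohortConfig, simulate_cohort, simulate_recording, subjects_to_frame
from .stats import brain_behavior, demographic_comparisons, trajectory_analysis

log = logging.getLogger("nirsnet.pipeline")

CHROMOPHORES = ("HbO", "HbR")


@dataclass
class RunConfig:
    out_dir: str = "nirsnet_run"
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    chromophores: tuple[str, ...] = CHROMOPHORES
    n_null: int = 100
    fdr_q: float = 0.05
    do_preprocess: bool = True
    include_betweenness: bool = False

    def __post_init__(self) -> None:
        # the master seed drives the cohort unless the cohort seed was set explicitly
        if self.cohort.seed == 0 and self.seed != 0:
            self.cohort = dataclasses.replace(self.cohort, seed=self.seed)
        bad = set(self.chromophores) - set(CHROMOPHORES)
        if bad:
            raise ValueError(f"unknown chromophores: {sorted(bad)}")


@dataclass
class RunReport:
    stage_seconds: dict[str, float]
    counts: dict[str, int]
    artifact_percent_by_group: dict[str, float]
    n_fdr_significant: int
    out_dir: str


def _config_to_dict(cfg) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    return convert(cfg)


def config_from_dict(data: dict) -> RunConfig:
    """Build a RunConfig from a plain (e.g. YAML-loaded) dictionary."""
    from .simulate import EffectSpec, NoiseSpec

    data = dict(data)
    cohort = dict(data.pop("cohort", {}))
    if "noise" in cohort:
        cohort["noise"] = NoiseSpec(**cohort["noise"])
    if "effects" in cohort:
        cohort["effects"] = tuple(EffectSpec(**e) for e in cohort["effects"])
    if "age_range" in cohort:
        cohort["age_range"] = tuple(cohort["age_range"])
    pre = dict(data.pop("preprocess", {}))
    if "chromophores" in data:
        data["chromophores"] = tuple(data["chromophores"])
    return RunConfig(cohort=CohortConfig(**cohort), preprocess=PreprocessConfig(**pre), **data)


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(config: RunConfig) -> dict[str, int]:
    out = Path(config.out_dir)
    montage = make_montage()
    nio.write_table(montage, out / "montage.tsv")
    subjects, truth = simulate_cohort(config.cohort, montage)
    nio.write_table(subjects_to_frame(subjects), out / "subjects.tsv")
    for subject in subjects:
        series = simulate_recording(subject, montage, config.cohort, truth)
        nio.write_series(series, out / "series", subject.subject_id)
    log.info("simulate: wrote %d subjects", len(subjects))
    return {"subjects": len(subjects), "artifact_events": len(truth.artifact_log)}


def stage_preprocess(config: RunConfig) -> dict[str, int]:
    out = Path(config.out_dir)
    subjects = nio.read_table(out / "subjects.tsv")
    rows = []
    for rec in subjects.itertuples(index=False):
        series = nio.read_series(out / "series", rec.subject_id)
        result = clean_series(series, config.preprocess)
        nio.write_series(result.series, out / "clean", rec.subject_id)
        rows.append(
            {"subject_id": rec.subject_id, "group": rec.group,
             "artifact_percent": result.artifact_percent}
        )
    nio.write_table(pd.DataFrame(rows), out / "artifact_report.tsv")
    log.info("preprocess: cleaned %d subjects", len(rows))
    return {"subjects": len(rows)}


def stage_network(config: RunConfig) -> dict[str, int]:
    out = Path(config.out_dir)
    src = out / ("clean" if config.do_preprocess else "series")
    subjects = nio.read_table(out / "subjects.tsv")
    count = 0
    for rec in subjects.itertuples(index=False):
        series = nio.read_series(src, rec.subject_id)
        for chrom in config.chromophores:
            conn = correlation_matrix(series, chrom)
            nio.write_matrix(conn.z, out / "zmat" / f"{rec.subject_id}_{chrom}.tsv")
            count += 1
    log.info("network: wrote %d z-matrices", count)
    return {"matrices": count}


def stage_metrics(config: RunConfig) -> dict[str, int]:
    out = Path(config.out_dir)
    subjects = nio.read_table(out / "subjects.tsv")
    rows = []
    for si, rec in enumerate(subjects.itertuples(index=False)):
        for ci, chrom in enumerate(config.chromophores):
            z = nio.read_matrix(out / "zmat" / f"{rec.subject_id}_{chrom}.tsv")
            stack = threshold_by_sparsity(z)
            null_seed = int(
                np.random.SeedSequence([config.seed, 5, si, ci]).generate_state(1)[0]
                % (2**31)
            )
            sm = compute_subject_metrics(
                stack, n_null=config.n_null, seed=null_seed,
                include_betweenness=config.include_betweenness,
            )
            for curve in (sm.e_glob, sm.e_loc, sm.e_glob_norm, sm.e_loc_norm):
                if curve is None:
                    continue
                rows.append(
                    {"subject_id": rec.subject_id, "chromophore": chrom,
                     "metric": curve.name, "channel": "global", "auc": curve.auc}
                )
            for name, aucs in (
                ("degree", sm.nodal_auc("degree")),
                ("nodal_efficiency", sm.nodal_auc("nodal_efficiency")),
            ):
                for ch, val in enumerate(aucs, start=1):
                    rows.append(
                        {"subject_id": rec.subject_id, "chromophore": chrom,
                         "metric": name, "channel": ch, "auc": val}
                    )
    nio.write_table(pd.DataFrame(rows), out / "metrics.tsv")
    log.info("metrics: %d rows", len(rows))
    return {"metric_rows": len(rows)}


def stage_stats(config: RunConfig) -> dict[str, int]:
    out = Path(config.out_dir)
    subjects = nio.read_table(out / "subjects.tsv")
    metrics = nio.read_table(out / "metrics.tsv")
    fits = trajectory_analysis(metrics, subjects, q=config.fdr_q)
    nio.write_table(fits, out / "stats" / "trajectory_fits.tsv")
    behav = brain_behavior(metrics, subjects)
    nio.write_table(behav, out / "stats" / "partial_correlations.tsv")
    demo = demographic_comparisons(subjects)
    nio.write_table(demo, out / "stats" / "group_comparisons.tsv")
    log.info("stats: %d trajectory fits, %d partial correlations", len(fits), len(behav))
    return {
        "trajectory_rows": len(fits),
        "behavior_rows": len(behav),
        "fdr_significant": int(fits["fdr_significant"].sum()),
    }


STAGES = ("simulate", "preprocess", "network", "metrics", "stats")


def run_all(config: RunConfig) -> RunReport:
    """Execute all stages in order; identical config + seed → identical tables."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.json", "w") as fh:
        json.dump(_config_to_dict(config), fh, indent=2, sort_keys=True)

    timings: dict[str, float] = {}
    counts: dict[str, int] = {}
    stage_fns = {
        "simulate": stage_simulate,
        "preprocess": stage_preprocess,
        "network": stage_network,
        "metrics": stage_metrics,
        "stats": stage_stats,
    }
    for name in STAGES:
        if name == "preprocess" and not config.do_preprocess:
            log.info("preprocess: skipped by configuration")
            continue
        t0 = time.perf_counter()
        try:
            stage_counts = stage_fns[name](config)
        except Exception:
            log.exception("stage %s failed", name)
            raise
        timings[name] = time.perf_counter() - t0
        counts.update({f"{name}.{k}": v for k, v in stage_counts.items()})

    report_df = nio.read_table(out / "artifact_report.tsv") if config.do_preprocess else None
    artifact_by_group = (
        report_df.groupby("group")["artifact_percent"].mean().to_dict()
        if report_df is not None
        else {}
    )
    fits = nio.read_table(out / "stats" / "trajectory_fits.tsv")
    report = RunReport(
        stage_seconds=timings,
        counts=counts,
        artifact_percent_by_group={k: float(v) for k, v in artifact_by_group.items()},
        n_fdr_significant=int(fits["fdr_significant"].sum()),
        out_dir=str(out),
    )
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(dataclasses.asdict(report), fh, indent=2, sort_keys=True)
    return report


def validate_inputs(run_dir: str | Path) -> list[dict]:
    """Structural checks on a run directory; returns diagnostics, never raises."""
    run_dir = Path(run_dir)
    diagnostics: list[dict] = []

    def issue(level: str, message: str) -> None:
        diagnostics.append({"level": level, "message": message})

    montage_path = run_dir / "montage.tsv"
    if not montage_path.exists():
        issue("error", "montage.tsv missing")
    else:
        try:
            validate_montage(nio.read_table(montage_path))
        except ValueError as exc:
            issue("error", f"montage invalid: {exc}")

    subjects_path = run_dir / "subjects.tsv"
    if not subjects_path.exists():
        issue("error", "subjects.tsv missing")
        return diagnostics
    subjects = nio.read_table(subjects_path)
    required = {"subject_id", "group", "age", "viq", "piq", "fsiq"}
    missing = required - set(subjects.columns)
    if missing:
        issue("error", f"subjects.tsv missing columns: {sorted(missing)}")
        return diagnostics

    series_dir = run_dir / "series"
    rates = set()
    for sid in subjects["subject_id"]:
        for chrom in CHROMOPHORES:
            path = series_dir / f"{sid}_{chrom}.tsv"
            if not path.exists():
                issue("error", f"series file missing for subject {sid} ({chrom})")
    for sid in subjects["subject_id"][:5]:
        path = series_dir / f"{sid}_HbO.tsv"
        if path.exists():
            t = nio.read_table(path)["time"].to_numpy()
            if len(t) > 1:
                rates.add(round(1.0 / float(np.median(np.diff(t))), 3))
    if len(rates) > 1:
        issue("error", f"inconsistent sampling rates across subjects: {sorted(rates)}")
    return diagnostics
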