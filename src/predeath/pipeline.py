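"""Config-driven orchestration of the full analysis.

A run executes, in order: simulate (or ingest) -> preprocess -> label ->
train -> explain -> embed -> stratify, writing every intermediate artifact
as CSV into the output directory and finishing with a JSON manifest that
records the config hash, stage timings, artifact SHA-256 digests, package
versions and warnings.  Re-running over an output directory whose manifest
carries the same config hash skips completed stages and reloads their
artifacts, so each stage is independently testable and a run is resumable.

Every random draw descends from the single config seed; deterministic
stages reproduce bit-identical artifacts for identical configs.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .embedding import (embed_2d, missingness_filter, stack_state_matrices,
                        temporal_separation_score)
from .labeling import build_horizon_dataset, grouped_split
from .modeling import train_model_family
from .preprocess import CohortMatrices, dedup_first_per_day, coverage_filter, \
    resample_cohort
from .shap_behavior import behavior_matrix, compute_panels, \
    select_correct_positives
from .stratify import cluster_and_select_k, cluster_raw_values, \
    compare_partitions, subtype_behaviors, subtype_summary_and_tests
from .synthetic_cohort import generate_cohort, three_subtype_scenario

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

STAGES = ["simulate", "preprocess", "label", "train", "explain", "embed",
          "stratify"]


@dataclass
class PipelineConfig:
    """Everything a run needs; serializes losslessly to YAML."""

    # input: synthetic cohort (events_csv overrides when given)
    n_patients: int = 300
    seed: int = 0
    events_csv: str | None = None
    truth_csv: str | None = None
    # preprocessing
    window_days: int = 5
    align: str = "centered"
    coverage_fraction: float = 0.5
    t_max: int = 180
    # labeling
    horizons: tuple[int, ...] = (1, 15, 30, 45, 60, 75, 90)
    negative_day: int = 168
    min_observed: int = 1
    # modeling
    search_budget: int = 0
    cv_folds: int = 5
    # behavior
    threshold: float = 0.5
    attribution_subset: str = "all"
    # embedding
    embed_method: str = "umap"
    max_missing: float = 0.10
    # stratification
    k: int | None = None
    k_min: int = 2
    k_max: int = 10
    alpha: float = 0.01
    # output
    outdir: str = "predeath_run"

    def validate(self) -> None:
        if not self.horizons:
            raise ValueError("horizons must be non-empty")
        if any(not 1 <= n < self.negative_day for n in self.horizons):
            raise ValueError("every horizon must satisfy 1 <= n < "
                             f"negative_day ({self.negative_day})")
        if self.negative_day > self.t_max:
            raise ValueError("negative_day must be <= t_max")
        if self.embed_method not in ("umap", "tsne", "pca"):
            raise ValueError(f"unknown embed_method {self.embed_method!r}")
        if not 0 < self.max_missing <= 1:
            raise ValueError("max_missing must be in (0, 1]")
        if self.k is not None and self.k < 2:
            raise ValueError("k must be >= 2")
        if not 2 <= self.k_min <= self.k_max:
            raise ValueError("need 2 <= k_min <= k_max")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["horizons"] = list(d["horizons"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "horizons" in d:
            d["horizons"] = tuple(int(h) for h in d["horizons"])
        return cls(**d)


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages_completed: list[str] = field(default_factory=list)
    timings: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)
    report: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def save(self, outdir: Path) -> None:
        path = outdir / "manifest.json"
        payload = {
            "config_hash": self.config_hash,
            "version": self.version,
            "stages_completed": self.stages_completed,
            "timings": self.timings,
            "artifacts": self.artifacts,
            "report": self.report,
            "warnings": self.warnings,
        }
        path.write_text(json.dumps(payload, indent=2, default=float))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, manifest: RunManifest,
               **kwargs) -> None:
    df.to_csv(path, **kwargs)
    manifest.artifacts[path.name] = _sha256(path)


class _Run:
    """Mutable in-memory state threaded through the stages."""

    def __init__(self, config: PipelineConfig, manifest: RunManifest,
                 outdir: Path, cached: set[str]):
        self.cfg = config
        self.manifest = manifest
        self.outdir = outdir
        self.cached = cached
        self.events = None
        self.truth = None
        self.matrices: CohortMatrices | None = None
        self.datasets = {}
        self.split = None
        self.family = None
        self.panels = None
        self.correct = None


def _stage_simulate(run: _Run) -> None:
    cfg = run.cfg
    if cfg.events_csv is not None:
        run.events = pd.read_csv(cfg.events_csv)
        if cfg.truth_csv is not None:
            run.truth = pd.read_csv(cfg.truth_csv)
        return
    if "simulate" in run.cached:
        run.events = pd.read_csv(run.outdir / "events.csv")
        run.truth = pd.read_csv(run.outdir / "truth.csv")
        return
    spec, params = three_subtype_scenario(n_patients=cfg.n_patients,
                                          seed=cfg.seed)
    run.events, run.truth = generate_cohort(spec, params)
    _write_csv(run.events, run.outdir / "events.csv", run.manifest,
               index=False)
    _write_csv(run.truth, run.outdir / "truth.csv", run.manifest, index=False)


def _stage_preprocess(run: _Run) -> None:
    cfg = run.cfg
    events = dedup_first_per_day(run.events)
    kept, excluded = coverage_filter(events, cfg.coverage_fraction)
    if excluded:
        events = events[~events["patient_id"].isin(excluded)]
        run.manifest.warnings.append(
            f"{len(excluded)} patients lacked a retained parameter entirely "
            "and were excluded")
    run.matrices = resample_cohort(events, window_days=cfg.window_days,
                                   t_max=cfg.t_max, align=cfg.align,
                                   parameters=kept)
    days = sorted(set(cfg.horizons) | {cfg.negative_day})
    tidy = run.matrices.to_tidy()
    slice_ = tidy[tidy["day"].isin(days) & tidy["observed"]]
    _write_csv(slice_, run.outdir / "matrices_at_anchor_days.csv",
               run.manifest, index=False)


def _stage_label(run: _Run) -> None:
    cfg = run.cfg
    for n in cfg.horizons:
        ds = build_horizon_dataset(run.matrices, n,
                                   negative_day=cfg.negative_day,
                                   min_observed=cfg.min_observed)
        run.datasets[n] = ds
        _write_csv(ds.frame.assign(horizon=n),
                   run.outdir / f"dataset_h{n:03d}.csv", run.manifest,
                   index=False)
    run.split = grouped_split(run.datasets[cfg.horizons[0]], seed=cfg.seed)
    _write_csv(run.split, run.outdir / "split.csv", run.manifest, index=False)


def _stage_train(run: _Run) -> None:
    cfg = run.cfg
    run.family = train_model_family(
        run.matrices, horizons=list(cfg.horizons),
        negative_day=cfg.negative_day, min_observed=cfg.min_observed,
        search_budget=cfg.search_budget, cv_folds=cfg.cv_folds, seed=cfg.seed)
    _write_csv(run.family.metrics, run.outdir / "metrics.csv", run.manifest,
               index=False)
    for n, model in run.family.models.items():
        path = run.outdir / f"model_h{n:03d}.txt"
        model.booster.booster_.save_model(str(path))
        run.manifest.artifacts[path.name] = _sha256(path)
    run.manifest.report["auroc_horizon_spearman"] = \
        run.family.auroc_horizon_spearman()


def _stage_explain(run: _Run) -> None:
    cfg = run.cfg
    run.panels = compute_panels(run.family, run.datasets, split=run.split,
                                subset=cfg.attribution_subset)
    run.correct = {n: select_correct_positives(p, cfg.threshold)
                   for n, p in run.panels.items()}
    behavior = behavior_matrix(run.correct, already_filtered=True)
    out = behavior.scaled.copy()
    out.loc["_scale"] = behavior.scale
    out.loc["_n_rows"] = behavior.n_rows
    _write_csv(out, run.outdir / "behavior_matrix.csv", run.manifest,
               index_label="feature")
    tidy = pd.concat([p.to_tidy() for p in run.correct.values()],
                     ignore_index=True)
    _write_csv(tidy, run.outdir / "panels.csv", run.manifest, index=False)


def _stage_embed(run: _Run) -> None:
    cfg = run.cfg
    feats = missingness_filter(run.matrices, horizons=cfg.horizons,
                               max_missing=cfg.max_missing)
    run.manifest.report["embedding_features_kept"] = len(feats)
    stacked = stack_state_matrices(run.matrices, run.correct, feats)
    frames = []
    for variant, X in [("attribution", stacked.attribution),
                       ("raw", stacked.raw)]:
        coords = embed_2d(X, method=cfg.embed_method, seed=cfg.seed)
        run.manifest.report[f"temporal_separation_{variant}"] = \
            temporal_separation_score(coords)
        out = coords.reset_index()
        out.insert(2, "method", cfg.embed_method)
        out.insert(3, "variant", variant)
        frames.append(out)
    _write_csv(pd.concat(frames, ignore_index=True),
               run.outdir / "embedding.csv", run.manifest, index=False)


def _stage_stratify(run: _Run) -> None:
    cfg = run.cfg
    day1 = min(cfg.horizons)
    panel = run.correct[day1]
    result = cluster_and_select_k(panel, k_range=range(cfg.k_min,
                                                       cfg.k_max + 1),
                                  k=cfg.k)
    _write_csv(result.labels.rename("subtype").reset_index(),
               run.outdir / "subtypes.csv", run.manifest, index=False)
    curves = pd.DataFrame({"k": result.silhouette.index,
                           "silhouette": result.silhouette.values,
                           "within_variance":
                               result.within_variance.values})
    _write_csv(curves, run.outdir / "k_selection.csv", run.manifest,
               index=False)
    run.manifest.report["k_selected"] = result.k
    run.manifest.report["subtype_sizes"] = result.sizes.to_dict()

    day1_values = run.matrices.day_frame(day1).loc[result.labels.index]
    raw_result = cluster_raw_values(day1_values,
                                    k_range=range(cfg.k_min, cfg.k_max + 1),
                                    k=cfg.k)
    _write_csv(raw_result.labels.rename("subtype").reset_index(),
               run.outdir / "subtypes_raw.csv", run.manifest, index=False)

    focus = [f for f in ("alb", "crp", "bun", "ldh")
             if f in day1_values.columns] or list(day1_values.columns[:4])
    summary = subtype_summary_and_tests(result.labels, day1_values[focus],
                                        alpha=cfg.alpha)
    _write_csv(summary.lab_summary, run.outdir / "subtype_summary.csv",
               run.manifest)
    _write_csv(summary.tests, run.outdir / "subtype_tests.csv", run.manifest,
               index=False)

    per_sub = subtype_behaviors(result.labels, run.correct)
    for s, bm in per_sub.items():
        out = bm.scaled.copy()
        out.loc["_scale"] = bm.scale
        out.loc["_n_rows"] = bm.n_rows
        _write_csv(out, run.outdir / f"behavior_subtype{s}.csv",
                   run.manifest, index_label="feature")

    if run.truth is not None and "subtype" in run.truth.columns:
        truth = run.truth.set_index("patient_id")["subtype"]
        run.manifest.report["ari_attribution_vs_truth"] = \
            compare_partitions(result.labels, truth)
        run.manifest.report["ari_raw_vs_truth"] = \
            compare_partitions(raw_result.labels, truth)


_STAGE_FN = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "label": _stage_label,
    "train": _stage_train,
    "explain": _stage_explain,
    "embed": _stage_embed,
    "stratify": _stage_stratify,
}


def run_pipeline(config: PipelineConfig,
                 stop_after: str | None = None) -> RunManifest:
    """Execute the pipeline; returns the manifest (also written to disk).

    ``stop_after`` truncates the stage list (e.g. ``"train"``); later
    invocations with the same config resume from the cached artifacts.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    cached: set[str] = set()
    prev_path = outdir / "manifest.json"
    if prev_path.exists():
        prev = json.loads(prev_path.read_text())
        if prev.get("config_hash") == config.config_hash():
            cached = set(prev.get("stages_completed", []))

    manifest = RunManifest(config_hash=config.config_hash(),
                           version=__version__)
    run = _Run(config, manifest, outdir, cached)
    stages = STAGES[:STAGES.index(stop_after) + 1] if stop_after else STAGES
    for stage in stages:
        t0 = time.time()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                _STAGE_FN[stage](run)
            except Exception:
                manifest.save(outdir)
                raise
        manifest.warnings.extend(f"{stage}: {w.message}" for w in caught)
        manifest.timings[stage] = round(time.time() - t0, 3)
        manifest.stages_completed.append(stage)
    manifest.save(outdir)
    return manifest
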