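"""End-to-end orchestration: cohort -> networks -> selection/classification ->
reproducibility aggregation -> effect sizes, with full parameter provenance.

A run is driven by a single :class:`PipelineConfig` (readable from YAML; CLI
flags override config keys).  All stage outputs land in the output directory
and a machine-readable ``summary.json`` collects parameters, per-scheme
accuracies and the final top edges with their effect sizes.  Two runs with
the same config and seed produce byte-identical summaries.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .aggregate import (
    ReproducibilityReport,
    SchemeRanking,
    aggregate_across_measurements,
    aggregate_across_schemes,
    plot_top_edges,
    roi_hub_counts,
    write_edge_list,
    write_report_csv,
)
from .cmn import (
    CorticalAttributeTable,
    EdgeIndexMap,
    build_feature_table,
    read_tidy_csv,
)
from .cv import COST_GRID, ClassificationResult, CVScheme, accuracy_report, run_cv, scheme_feature_weights
from .effects import effect_table, effects_to_frame
from .infs import InfsParams
from .synthetic import Cohort, SyntheticConfig, config_from_dict, simulate_cohort

logger = logging.getLogger(__name__)

DEFAULT_SCHEMES = ("loo", "5fold", "10fold")


class PipelineError(ValueError):
    pass


def scheme_from_name(name: str, seed: int, stratified: bool = True) -> CVScheme:
    if name == "loo":
        return CVScheme("loo", seed=seed, stratified=stratified)
    if name.endswith("fold"):
        try:
            n_folds = int(name[: -len("fold")])
        except ValueError:
            raise PipelineError(f"unrecognized scheme name {name!r}") from None
        return CVScheme("kfold", n_folds=n_folds, seed=seed, stratified=stratified)
    raise PipelineError(f"unrecognized scheme name {name!r}")


@dataclass
class PipelineConfig:
    """Everything a run needs; exactly one of ``input_csv`` / ``synthetic``."""

    input_csv: str | None = None
    synthetic: SyntheticConfig | None = None
    hemispheres: tuple[str, ...] | None = None
    measurements: tuple[str, ...] | None = None
    alpha: float = 0.5
    r: float = 0.01
    standardize: bool = False
    top_k: int = 100
    k_f: int = 5
    schemes: tuple[str, ...] = DEFAULT_SCHEMES
    seed: int = 42
    classify: bool = True
    normalize_weights: bool = True
    make_plot: bool = False
    output_dir: str = "cmnet-run"

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        raw = dict(raw)
        synthetic = raw.pop("synthetic", None)
        if synthetic is not None:
            synthetic = config_from_dict(synthetic)
        for key in ("hemispheres", "measurements", "schemes"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(synthetic=synthetic, **raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, Mapping):
            raise PipelineError(f"config file {path} is not a key/value mapping")
        return cls.from_dict(raw)

    def infs_params(self) -> InfsParams:
        return InfsParams(alpha=self.alpha, r=self.r, standardize=self.standardize)


def validate_config(config: PipelineConfig) -> list[str]:
    """Collect invariant violations; an empty list means the config is valid."""
    problems: list[str] = []
    if config.input_csv is None and config.synthetic is None:
        problems.append("input: one of input_csv or synthetic is required")
    if config.input_csv is not None and config.synthetic is not None:
        problems.append("input: input_csv and synthetic are mutually exclusive")
    if config.input_csv is not None and not Path(config.input_csv).exists():
        problems.append(f"input_csv: path does not exist: {config.input_csv}")
    if not (0.0 <= config.alpha <= 1.0):
        problems.append(f"alpha: must be in [0, 1], got {config.alpha}")
    if config.r <= 0:
        problems.append(f"r: must be positive, got {config.r}")
    if config.top_k < 1:
        problems.append(f"top_k: must be >= 1, got {config.top_k}")
    if config.k_f < 1:
        problems.append(f"k_f: must be >= 1, got {config.k_f}")
    if not config.schemes:
        problems.append("schemes: at least one scheme is required")
    for name in config.schemes:
        try:
            scheme_from_name(name, config.seed)
        except PipelineError as exc:
            problems.append(f"schemes: {exc}")
    if config.synthetic is not None:
        n_f = config.synthetic.n_rois * (config.synthetic.n_rois - 1) // 2
        if config.k_f > n_f:
            problems.append(f"k_f: {config.k_f} exceeds n_f={n_f}")
        if config.top_k > n_f:
            problems.append(f"top_k: {config.top_k} exceeds n_f={n_f}")
    return problems


def _load_tables(config: PipelineConfig) -> tuple[dict, Cohort | None]:
    if config.synthetic is not None:
        cohort = simulate_cohort(config.synthetic)
        return dict(cohort.tables), cohort
    tables = read_tidy_csv(config.input_csv)
    return tables, None


def run_pipeline(config: PipelineConfig, output_dir: str | Path | None = None) -> dict:
    """Execute all stages and return the summary dict (also written as JSON)."""
    problems = validate_config(config)
    if problems:
        raise PipelineError("invalid pipeline config: " + "; ".join(problems))
    outdir = Path(output_dir if output_dir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    tables, cohort = _load_tables(config)
    if cohort is not None:
        cohort.write_csv(outdir / "cohort.csv")
        cohort.write_truth_csv(outdir / "truth.csv")
    logger.info("stage simulate/load: %.2fs", time.perf_counter() - t0)

    hemispheres = config.hemispheres or tuple(sorted({h for _, h in tables}))
    measurements = config.measurements or tuple(sorted({m for m, _ in tables}))
    missing = [
        (m, h) for h in hemispheres for m in measurements if (m, h) not in tables
    ]
    if missing:
        raise PipelineError(f"stage build-cmn: missing input tables for {missing}")

    infs_params = config.infs_params()
    cv_results: list[ClassificationResult] = []
    tuned_costs: dict[str, list[float]] = {}
    reports: dict[str, ReproducibilityReport] = {}
    summary: dict = {
        "parameters": {
            "alpha": config.alpha,
            "r": config.r,
            "standardize": config.standardize,
            "top_k": config.top_k,
            "k_f": config.k_f,
            "schemes": list(config.schemes),
            "seed": config.seed,
            "cost_grid": list(COST_GRID),
            "classify": config.classify,
            "normalize_weights": config.normalize_weights,
            "measurements": list(measurements),
            "hemispheres": list(hemispheres),
        },
        "final_top": {},
        "hubs": {},
    }

    for hemisphere in hemispheres:
        per_measurement: dict[str, dict[int, float]] = {}
        any_table: CorticalAttributeTable | None = None
        for measurement in measurements:
            table = tables[(measurement, hemisphere)]
            any_table = table
            t1 = time.perf_counter()
            features = build_feature_table(table)
            index_map = EdgeIndexMap(table.n_rois)
            edge_names = index_map.edge_names(table.roi_names)
            rankings: list[SchemeRanking] = []
            for name in config.schemes:
                scheme = scheme_from_name(name, config.seed)
                if config.classify:
                    result = run_cv(
                        features, table.labels, scheme,
                        top_k=min(config.top_k, features.shape[1]),
                        infs_params=infs_params,
                        measurement=measurement, hemisphere=hemisphere,
                    )
                    cv_results.append(result)
                    tuned_costs[f"{hemisphere}/{measurement}/{name}"] = result.tuned_costs
                    fold_scores = result.fold_scores
                else:
                    fold_scores = scheme_feature_weights(
                        features, table.labels, scheme, infs_params
                    )
                ranking = SchemeRanking.from_fold_scores(
                    fold_scores, name, measurement, hemisphere, config.k_f
                )
                rankings.append(ranking)
                _write_weights_csv(
                    outdir / f"weights_{hemisphere}_{measurement}_{name}.csv",
                    edge_names, ranking.weights,
                )
            per_measurement[measurement] = aggregate_across_schemes(
                rankings, normalize=config.normalize_weights
            )
            logger.info(
                "stage select/classify %s/%s: %.2fs",
                hemisphere, measurement, time.perf_counter() - t1,
            )

        assert any_table is not None
        index_map = EdgeIndexMap(any_table.n_rois)
        report = aggregate_across_measurements(
            per_measurement, config.k_f, index_map, any_table.roi_names, hemisphere
        )
        report.effect_sizes = _final_edge_effects(
            report, tables, measurements, hemisphere, index_map
        )
        reports[hemisphere] = report
        write_report_csv(report, outdir / f"report_{hemisphere}.csv")
        write_edge_list(report, outdir / f"edges_{hemisphere}.tsv")
        if config.make_plot:
            plot_top_edges(report, any_table.roi_names, outdir / f"top_edges_{hemisphere}.png")
        summary["final_top"][hemisphere] = [
            {
                "rank": e.rank,
                "roi_a": e.roi_a,
                "roi_b": e.roi_b,
                "weight": round(e.weight, 10),
                "cohens_d": _lookup_d(report, e),
            }
            for e in report.final_top
        ]
        summary["hubs"][hemisphere] = roi_hub_counts(report)

    if config.classify:
        acc = accuracy_report(cv_results)
        acc.to_csv(outdir / "accuracies.csv", index=False)
        summary["accuracies"] = [
            {k: (round(v, 10) if isinstance(v, float) else v) for k, v in row.items()}
            for row in acc.to_dict(orient="records")
        ]
        with open(outdir / "tuned_costs.json", "w") as fh:
            json.dump(tuned_costs, fh, indent=1, sort_keys=True)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    logger.info("pipeline total: %.2fs", time.perf_counter() - t0)
    return summary


def _write_weights_csv(path: Path, edge_names: Sequence[str], weights: np.ndarray) -> None:
    from .infs import rank_features

    order = rank_features(weights).ranks
    position = np.empty_like(order)
    position[order] = np.arange(order.shape[0])
    with open(path, "w") as fh:
        fh.write("edge_name,score,rank\n")
        for k, name in enumerate(edge_names):
            fh.write(f"{name},{weights[k]:.10g},{int(position[k])}\n")


def _final_edge_effects(
    report: ReproducibilityReport,
    tables: Mapping,
    measurements: Sequence[str],
    hemisphere: str,
    index_map: EdgeIndexMap,
):
    """Per-measurement d for every final edge; ``cohens_d`` is the d of the
    measurement in which the edge carries its largest averaged weight."""
    import pandas as pd

    if not report.final_top:
        return pd.DataFrame(columns=["roi_a", "roi_b", "cohens_d"])
    edge_pairs = [(e.roi_a, e.roi_b) for e in report.final_top]
    per_meas_d: dict[str, dict[tuple[str, str], float]] = {}
    for measurement in measurements:
        table = tables[(measurement, hemisphere)]
        features = build_feature_table(table)
        effects = effect_table(
            features, table.labels, edge_pairs, index_map, table.roi_names
        )
        per_meas_d[measurement] = {e.edge: e.d for e in effects}
    rows = []
    for edge in report.final_top:
        pair = (edge.roi_a, edge.roi_b)
        weights = {
            m: report.per_measurement_union[m].get(edge.edge_index, 0.0)
            for m in measurements
        }
        source = max(sorted(weights), key=lambda m: weights[m])
        row = {"roi_a": edge.roi_a, "roi_b": edge.roi_b}
        for m in measurements:
            row[f"d_{m}"] = per_meas_d[m][pair]
        row["cohens_d"] = per_meas_d[source][pair]
        rows.append(row)
    return pd.DataFrame(rows)


def _lookup_d(report: ReproducibilityReport, edge) -> float:
    frame = report.effect_sizes
    if frame is None or frame.empty:
        return float("nan")
    hit = frame[(frame["roi_a"] == edge.roi_a) & (frame["roi_b"] == edge.roi_b)]
    return round(float(hit["cohens_d"].iloc[0]), 10)
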