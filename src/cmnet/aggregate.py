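"""Cross-scheme and cross-measurement reproducibility aggregation.

Per scheme, a feature's weight is the mean of its selection score over that
scheme's outer training folds.  Weights are min-max normalized to [0, 1]
within each scheme before averaging (score magnitudes vary with fold size,
so averaging is only meaningful on a common scale; raw-scale averaging is
available behind a flag).  An edge absent from a scheme's top set
contributes 0 to the average, penalizing non-reproducible edges.  The same
absent-as-zero mean is applied again across measurements, and the final
top-k edges are reported as ROI-name pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cmn import EdgeIndexMap
from .infs import rank_features


class AggregationError(ValueError):
    pass


@dataclass
class SchemeRanking:
    """One scheme's aggregated feature weights for a (measurement, hemisphere)."""

    scheme_name: str
    measurement: str
    hemisphere: str
    weights: np.ndarray
    k_f: int
    top_set: np.ndarray

    @classmethod
    def from_fold_scores(
        cls,
        fold_scores: np.ndarray,
        scheme_name: str,
        measurement: str,
        hemisphere: str,
        k_f: int,
    ) -> "SchemeRanking":
        fold_scores = np.asarray(fold_scores, dtype=float)
        if fold_scores.ndim != 2:
            raise AggregationError("fold_scores must be n_folds x n_features")
        weights = fold_scores.mean(axis=0)
        if not np.all(np.isfinite(weights)):
            raise AggregationError("non-finite aggregated weights")
        if not (1 <= k_f <= weights.shape[0]):
            raise AggregationError(f"k_f={k_f} out of range")
        top_set = rank_features(weights).ranks[:k_f]
        return cls(scheme_name, measurement, hemisphere, weights, k_f, top_set)


@dataclass
class FinalEdge:
    rank: int
    edge_index: int
    roi_a: str
    roi_b: str
    weight: float


@dataclass
class ReproducibilityReport:
    """Final cross-scheme, cross-measurement top edges for one hemisphere."""

    hemisphere: str
    k_f: int
    per_measurement_union: dict[str, dict[int, float]]
    final_top: list[FinalEdge]
    effect_sizes: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        measurements = sorted(self.per_measurement_union)
        rows = []
        for edge in self.final_top:
            row: dict[str, object] = {
                "rank": edge.rank,
                "roi_a": edge.roi_a,
                "roi_b": edge.roi_b,
            }
            for m in measurements:
                row[f"weight_{m}"] = self.per_measurement_union[m].get(edge.edge_index, 0.0)
            row["averaged_weight"] = edge.weight
            rows.append(row)
        frame = pd.DataFrame(rows)
        if self.effect_sizes is not None and not frame.empty:
            frame = frame.merge(self.effect_sizes, on=["roi_a", "roi_b"], how="left")
        return frame


def _minmax(weights: np.ndarray) -> np.ndarray:
    lo, hi = float(weights.min()), float(weights.max())
    if hi == lo:
        return np.zeros_like(weights)  # no ranking information
    return (weights - lo) / (hi - lo)


def aggregate_across_schemes(
    rankings: Sequence[SchemeRanking],
    normalize: bool = True,
) -> dict[int, float]:
    """Union of the schemes' top sets with absent-as-zero averaged weights."""
    if not rankings:
        raise AggregationError("no scheme rankings given")
    contexts = {(r.measurement, r.hemisphere) for r in rankings}
    if len(contexts) != 1:
        raise AggregationError(f"mixed (measurement, hemisphere) contexts: {contexts}")
    names = [r.scheme_name for r in rankings]
    if len(set(names)) != len(names):
        raise AggregationError(f"duplicate scheme names: {names}")
    union = sorted({int(i) for r in rankings for i in r.top_set})
    out: dict[int, float] = {}
    for edge in union:
        total = 0.0
        for r in rankings:
            if edge in set(int(i) for i in r.top_set):
                w = _minmax(r.weights) if normalize else r.weights
                total += float(w[edge])
        out[edge] = total / len(rankings)
    return out


def aggregate_across_measurements(
    per_measurement: Mapping[str, Mapping[int, float]],
    k_f: int,
    index_map: EdgeIndexMap,
    roi_names: Sequence[str],
    hemisphere: str = "",
) -> ReproducibilityReport:
    """Average edge weights across measurements (absent = 0) and keep the top k_f.

    Ties are broken by ascending edge index so the report is deterministic.
    """
    if not per_measurement:
        raise AggregationError("no per-measurement edge maps given")
    if k_f < 1:
        raise AggregationError("k_f must be >= 1")
    n_meas = len(per_measurement)
    union = sorted({e for edges in per_measurement.values() for e in edges})
    averaged = {
        e: sum(edges.get(e, 0.0) for edges in per_measurement.values()) / n_meas
        for e in union
    }
    ordered = sorted(averaged.items(), key=lambda item: (-item[1], item[0]))
    names = list(roi_names)
    final = []
    for rank, (edge, weight) in enumerate(ordered[:k_f], start=1):
        i, j = index_map.pairs[edge]
        final.append(FinalEdge(rank, edge, names[i], names[j], weight))
    return ReproducibilityReport(
        hemisphere=hemisphere,
        k_f=k_f,
        per_measurement_union={m: dict(v) for m, v in per_measurement.items()},
        final_top=final,
    )


def roi_hub_counts(report: ReproducibilityReport) -> dict[str, int]:
    """How often each ROI is incident to a final top edge (hub listing)."""
    counts: dict[str, int] = {}
    for edge in report.final_top:
        for roi in (edge.roi_a, edge.roi_b):
            counts[roi] = counts.get(roi, 0) + 1
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))


def write_report_csv(report: ReproducibilityReport, path: str | Path) -> None:
    report.to_frame().to_csv(path, index=False)


def write_edge_list(report: ReproducibilityReport, path: str | Path) -> None:
    """Plain ranked edge list consumable by circular-graph plotting tools."""
    with open(path, "w") as fh:
        fh.write("rank\troi_a\troi_b\tweight\n")
        for edge in report.final_top:
            fh.write(f"{edge.rank}\t{edge.roi_a}\t{edge.roi_b}\t{edge.weight:.6g}\n")


def plot_top_edges(
    report: ReproducibilityReport, roi_names: Sequence[str], path: str | Path
) -> None:
    """Minimal circular layout: ROIs on a circle, top edges as chords."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(roi_names)
    angles = 2 * np.pi * np.arange(n) / n
    xs, ys = np.cos(angles), np.sin(angles)
    fig, ax = plt.subplots(figsize=(7, 7))
    ax.scatter(xs, ys, s=12, color="0.3", zorder=3)
    for k, name in enumerate(roi_names):
        ax.annotate(
            name, (1.06 * xs[k], 1.06 * ys[k]),
            fontsize=6, ha="center", va="center",
            rotation=np.degrees(angles[k]) if xs[k] >= 0 else np.degrees(angles[k]) + 180,
        )
    max_w = max((e.weight for e in report.final_top), default=1.0) or 1.0
    name_to_idx = {name: k for k, name in enumerate(roi_names)}
    for edge in report.final_top:
        i, j = name_to_idx[edge.roi_a], name_to_idx[edge.roi_b]
        ax.plot(
            [xs[i], xs[j]], [ys[i], ys[j]],
            lw=0.5 + 2.5 * edge.weight / max_w, alpha=0.8,
        )
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(f"top {report.k_f} edges ({report.hemisphere})", fontsize=10)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
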