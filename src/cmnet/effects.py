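"""Cohen's d effect sizes for connection values between two groups.

The statistic is the absolute group mean difference divided by the plain
average of the two group standard deviations:

    d = |mean_a - mean_b| / ((sd_a + sd_b) / 2)

with sample (n-1) standard deviations.  Note the statistic is nonnegative
and unbounded above; it is reported as computed, never clipped.  Banding
follows Cohen's conventional thresholds: 0.8 large, 0.5 medium, 0.2 small.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cmn import EdgeIndexMap

BAND_LARGE = 0.8
BAND_MEDIUM = 0.5
BAND_SMALL = 0.2


class EffectSizeError(ValueError):
    pass


@dataclass(frozen=True)
class EdgeEffect:
    """Group statistics and effect size of one connection."""

    edge: tuple[str, str]
    mu_a: float
    mu_b: float
    sigma_a: float
    sigma_b: float
    d: float

    @property
    def band(self) -> str:
        return effect_band(self.d)


def effect_band(d: float) -> str:
    if d >= BAND_LARGE:
        return "large"
    if d >= BAND_MEDIUM:
        return "medium"
    if d >= BAND_SMALL:
        return "small"
    return "n.s."


def cohens_d(
    values_a: np.ndarray,
    values_b: np.ndarray,
    edge: tuple[str, str] = ("a", "b"),
) -> EdgeEffect:
    """Effect size between two groups of connection values.

    Both-degenerate groups (sd 0 each) with equal means give d = 0; with
    unequal means the statistic is undefined and raises, naming the edge.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise EffectSizeError("need at least 2 values per group")
    mu_a, mu_b = float(a.mean()), float(b.mean())
    sigma_a, sigma_b = float(a.std(ddof=1)), float(b.std(ddof=1))
    stdm = (sigma_a + sigma_b) / 2.0
    diff = abs(mu_a - mu_b)
    if stdm == 0.0:
        if diff == 0.0:
            d = 0.0
        else:
            raise EffectSizeError(
                f"effect size undefined for edge {edge}: both group sds are zero "
                "but the means differ"
            )
    else:
        d = diff / stdm
    return EdgeEffect(tuple(edge), mu_a, mu_b, sigma_a, sigma_b, d)


def effect_table(
    feature_table: np.ndarray,
    labels: np.ndarray,
    edges: Sequence[tuple[str, str]] | Sequence[str],
    index_map: EdgeIndexMap,
    roi_names: Sequence[str],
) -> list[EdgeEffect]:
    """Cohen's d for the requested edges, computed on the full cohort.

    ``edges`` are (roi_a, roi_b) pairs or "roiA|roiB" strings; the result is
    sorted by d descending (ties by edge name).
    """
    X = np.asarray(feature_table, dtype=float)
    y = np.asarray(labels)
    groups = np.unique(y)
    if groups.shape[0] != 2:
        raise EffectSizeError(f"expected 2 groups, found {groups.tolist()}")
    names = list(roi_names)
    name_to_idx = {n: i for i, n in enumerate(names)}
    out = []
    for edge in edges:
        if isinstance(edge, str):
            parts = edge.split("|")
            if len(parts) != 2:
                raise EffectSizeError(f"malformed edge name {edge!r}")
            roi_a, roi_b = parts
        else:
            roi_a, roi_b = edge
        for roi in (roi_a, roi_b):
            if roi not in name_to_idx:
                raise EffectSizeError(f"unknown ROI name {roi!r}")
        col = index_map.index(name_to_idx[roi_a], name_to_idx[roi_b])
        out.append(
            cohens_d(X[y == groups[0], col], X[y == groups[1], col], (roi_a, roi_b))
        )
    out.sort(key=lambda e: (-e.d, e.edge))
    return out


def effects_to_frame(
    effects: Sequence[EdgeEffect],
    hemisphere: str | None = None,
    measurement: str | None = None,
) -> pd.DataFrame:
    rows = []
    for e in effects:
        row: dict[str, object] = {}
        if hemisphere is not None:
            row["hemisphere"] = hemisphere
        if measurement is not None:
            row["measurement"] = measurement
        row.update(
            roi_a=e.edge[0], roi_b=e.edge[1], mu_a=e.mu_a, mu_b=e.mu_b,
            sigma_a=e.sigma_a, sigma_b=e.sigma_b, d=e.d, band=e.band,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def write_effects_csv(
    effects: Sequence[EdgeEffect],
    path: str | Path,
    hemisphere: str | None = None,
    measurement: str | None = None,
) -> None:
    effects_to_frame(effects, hemisphere, measurement).to_csv(path, index=False)
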