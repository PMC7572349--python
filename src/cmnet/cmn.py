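"""Cortical morphological network (CMN) construction and vectorization.

A CMN is a per-subject, per-measurement, per-hemisphere symmetric matrix
whose entry ``(i, j)`` is the absolute difference between the ROI-averaged
attribute values of regions ``i`` and ``j``.  Two regions with similar
morphology are therefore connected with a weight near zero.  Because the
matrix is symmetric with a zero diagonal, each network is represented by the
strict upper triangle, flattened row-major into a feature vector of length
``n_r * (n_r - 1) / 2`` (595 for a 35-region hemisphere).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .atlas import ROIParcellation

#: Measurement identifiers for the four attribute networks, in canonical order.
MEASUREMENTS: tuple[str, ...] = (
    "max_principal_curvature",
    "cortical_thickness",
    "sulcal_depth",
    "average_curvature",
)

TIDY_COLUMNS = ("subject_id", "group", "hemisphere", "measurement", "roi_name", "value")


class CMNValidationError(ValueError):
    """Raised when an input violates a CMN structural invariant."""


@dataclass
class CorticalAttributeTable:
    """ROI-level attribute values for one (measurement, hemisphere) context.

    ``values`` is a subjects x n_rois matrix of ROI-averaged attribute values;
    ``labels`` holds one binary group label per subject.
    """

    measurement: str
    hemisphere: str
    values: np.ndarray
    labels: np.ndarray
    subjects: list[str]
    roi_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise CMNValidationError("values must be a 2-D subjects x ROIs matrix")
        if self.values.shape[1] != len(self.roi_names):
            raise CMNValidationError(
                f"values has {self.values.shape[1]} columns but "
                f"{len(self.roi_names)} ROI names were given"
            )
        if self.values.shape[0] != len(self.labels) or len(self.subjects) != len(self.labels):
            raise CMNValidationError("subjects, labels and value rows must align")
        if not np.all(np.isfinite(self.values)):
            raise CMNValidationError("values contain missing or non-finite entries")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class EdgeIndexMap:
    """Fixed bijection between vector positions and unordered ROI pairs.

    Pair order is row-major over the strict upper triangle:
    (0,1), (0,2), ..., (0,n-1), (1,2), ...  This order must be identical
    across subjects, cross-validation schemes and reports.
    """

    n_rois: int
    pairs: tuple[tuple[int, int], ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.n_rois < 2:
            raise CMNValidationError("an edge map needs at least 2 ROIs")
        iu = np.triu_indices(self.n_rois, k=1)
        object.__setattr__(
            self, "pairs", tuple(zip(iu[0].tolist(), iu[1].tolist()))
        )

    def __len__(self) -> int:
        return self.n_rois * (self.n_rois - 1) // 2

    @property
    def n_features(self) -> int:
        return len(self)

    def index(self, i: int, j: int) -> int:
        """Vector position of the unordered pair (i, j)."""
        if i == j:
            raise CMNValidationError("diagonal entries are not features")
        i, j = (i, j) if i < j else (j, i)
        if not (0 <= i < j < self.n_rois):
            raise CMNValidationError(f"ROI pair ({i}, {j}) out of range")
        # row-major strict upper triangle offset
        return i * (2 * self.n_rois - i - 1) // 2 + (j - i - 1)

    def edge_names(self, roi_names: Iterable[str]) -> list[str]:
        names = list(roi_names)
        if len(names) != self.n_rois:
            raise CMNValidationError("roi_names length does not match the map")
        return [f"{names[i]}|{names[j]}" for i, j in self.pairs]


def average_roi_measurement(
    vertex_values: np.ndarray, parcellation: ROIParcellation
) -> np.ndarray:
    """ROI-average a per-vertex attribute field.

    Returns the arithmetic mean of the vertex values assigned to each ROI,
    in parcellation order.  An ROI with no assigned vertex is an error, never
    a silent zero.
    """
    if parcellation.vertex_assignment is None:
        raise CMNValidationError("parcellation carries no vertex assignment")
    values = np.asarray(vertex_values, dtype=float)
    assignment = parcellation.vertex_assignment
    if values.shape[-1] != assignment.shape[0]:
        raise CMNValidationError(
            f"{values.shape[-1]} vertex values for {assignment.shape[0]} assigned vertices"
        )
    counts = np.bincount(assignment, minlength=parcellation.n_rois)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        names = ", ".join(parcellation.roi_names[i] for i in empty)
        raise CMNValidationError(f"ROI(s) with zero assigned vertices: {names}")
    sums = np.zeros(values.shape[:-1] + (parcellation.n_rois,))
    if values.ndim == 1:
        np.add.at(sums, assignment, values)
    else:
        for r in range(parcellation.n_rois):
            sums[..., r] = values[..., assignment == r].sum(axis=-1)
    return sums / counts


def build_cmn(roi_means: np.ndarray) -> np.ndarray:
    """Morphological-distance matrix ``|m_i - m_j|`` from per-ROI means."""
    means = np.asarray(roi_means, dtype=float)
    if means.ndim != 1:
        raise CMNValidationError("roi_means must be a 1-D vector")
    if not np.all(np.isfinite(means)):
        raise CMNValidationError("roi_means contain non-finite values")
    matrix = np.abs(means[:, None] - means[None, :])
    np.fill_diagonal(matrix, 0.0)
    return matrix


def validate_cmn(matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise CMNValidationError("CMN must be a square matrix")
    if not np.all(np.isfinite(matrix)):
        raise CMNValidationError("CMN contains non-finite values")
    if not np.array_equal(matrix, matrix.T):
        raise CMNValidationError("CMN must be symmetric")
    if np.any(np.diagonal(matrix) != 0.0):
        raise CMNValidationError("CMN diagonal must be exactly zero")
    if np.any(matrix < 0):
        raise CMNValidationError("CMN entries must be nonnegative")
    return matrix


def vectorize_cmn(matrix: np.ndarray, index_map: EdgeIndexMap | None = None) -> np.ndarray:
    """Extract the strict upper triangle of a valid CMN as a feature vector."""
    matrix = validate_cmn(matrix)
    if index_map is None:
        index_map = EdgeIndexMap(matrix.shape[0])
    elif index_map.n_rois != matrix.shape[0]:
        raise CMNValidationError("index map size does not match the matrix")
    iu = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu]


def devectorize_cmn(vector: np.ndarray, index_map: EdgeIndexMap) -> np.ndarray:
    """Inverse of :func:`vectorize_cmn` (exact round trip)."""
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (len(index_map),):
        raise CMNValidationError(
            f"vector length {vector.shape} does not match map length {len(index_map)}"
        )
    n = index_map.n_rois
    matrix = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    matrix[iu] = vector
    return matrix + matrix.T


def build_feature_table(table: CorticalAttributeTable) -> np.ndarray:
    """Stack the vectorized CMN of every subject into a subjects x n_f matrix."""
    n_r = table.n_rois
    iu = np.triu_indices(n_r, k=1)
    return np.abs(table.values[:, iu[0]] - table.values[:, iu[1]])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_tidy_csv(
    path: str | Path | io.TextIOBase,
    parcellation: ROIParcellation | None = None,
) -> dict[tuple[str, str], CorticalAttributeTable]:
    """Read a tidy cohort CSV into one attribute table per (measurement, hemisphere).

    Expected columns: subject_id, group, hemisphere, measurement, roi_name,
    value.  ROI column order follows the parcellation when given, otherwise
    the sorted ROI names found in the file.
    """
    frame = pd.read_csv(path)
    missing = [c for c in TIDY_COLUMNS if c not in frame.columns]
    if missing:
        raise CMNValidationError(f"tidy CSV is missing columns: {missing}")
    roi_order = (
        list(parcellation.roi_names)
        if parcellation is not None
        else sorted(frame["roi_name"].unique())
    )
    tables: dict[tuple[str, str], CorticalAttributeTable] = {}
    group_by_subject = frame.drop_duplicates("subject_id").set_index("subject_id")["group"]
    for (measurement, hemisphere), chunk in frame.groupby(
        ["measurement", "hemisphere"], sort=True
    ):
        wide = chunk.pivot_table(
            index="subject_id", columns="roi_name", values="value", aggfunc="first"
        )
        unknown = set(wide.columns) - set(roi_order)
        if unknown:
            raise CMNValidationError(f"ROI names not in the parcellation: {sorted(unknown)}")
        wide = wide.reindex(columns=roi_order)
        if wide.isna().any().any():
            raise CMNValidationError(
                f"missing values in ({measurement}, {hemisphere}) table"
            )
        subjects = wide.index.tolist()
        tables[(measurement, hemisphere)] = CorticalAttributeTable(
            measurement=measurement,
            hemisphere=hemisphere,
            values=wide.to_numpy(),
            labels=group_by_subject.loc[subjects].to_numpy(),
            subjects=subjects,
            roi_names=tuple(roi_order),
        )
    return tables


def tables_to_tidy_frame(
    tables: Mapping[tuple[str, str], CorticalAttributeTable]
) -> pd.DataFrame:
    records = []
    for (measurement, hemisphere), table in sorted(tables.items()):
        for s, subject in enumerate(table.subjects):
            for r, roi in enumerate(table.roi_names):
                records.append(
                    (subject, table.labels[s], hemisphere, measurement, roi, table.values[s, r])
                )
    return pd.DataFrame.from_records(records, columns=TIDY_COLUMNS)


def read_aparc_stats(path: str | Path) -> pd.DataFrame:
    """Read a FreeSurfer aparc-stats-like whitespace table.

    Comment lines start with ``#``; a ``# ColHeaders ...`` comment, when
    present, names the columns (the FreeSurfer convention), otherwise the
    first non-comment line is taken as the header row.  Returns a DataFrame
    indexed by the first column (the structure name).
    """
    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("ColHeaders"):
                    header = body.split()[1:]
                continue
            rows.append(line.split())
    if not rows and header is None:
        raise CMNValidationError(f"no data rows in stats table {path}")
    if header is None:
        header, rows = rows[0], rows[1:]
    frame = pd.DataFrame(rows, columns=header)
    for col in frame.columns[1:]:
        frame[col] = pd.to_numeric(frame[col], errors="coerce")
    return frame.set_index(frame.columns[0])


def write_cmn_csv(matrix: np.ndarray, roi_names: Iterable[str], path: str | Path) -> None:
    names = list(roi_names)
    pd.DataFrame(validate_cmn(matrix), index=names, columns=names).to_csv(path)


def write_feature_table_csv(
    features: np.ndarray,
    subjects: list[str],
    index_map: EdgeIndexMap,
    roi_names: Iterable[str],
    path: str | Path,
) -> None:
    pd.DataFrame(
        features, index=pd.Index(subjects, name="subject_id"),
        columns=index_map.edge_names(roi_names),
    ).to_csv(path)
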