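"""Cortical parcellation fixtures.

The default parcellation is the 35-label Desikan-Killiany cortical set per
hemisphere, in alphabetical FreeSurfer ``aparc`` label order.  This order is
load-bearing: it defines row/column indexing of every connectivity matrix and
therefore the meaning of every vectorized feature position.  All reported
edges are named by ROI-name pairs, never by raw indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 35 Desikan-Killiany labels of one hemisphere (FreeSurfer ``aparc``
#: label table minus "unknown"), alphabetically ordered.
DK35_REGIONS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "corpuscallosum",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

HEMISPHERES: tuple[str, ...] = ("lh", "rh")


@dataclass(frozen=True)
class ROIParcellation:
    """Ordered list of ROI names, optionally with a vertex-to-ROI assignment.

    Parameters
    ----------
    roi_names
        Unique region names; their order fixes all matrix and vector indexing.
    vertex_assignment
        Optional integer array mapping each vertex to an ROI index in
        ``range(len(roi_names))``.
    """

    roi_names: tuple[str, ...]
    vertex_assignment: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        names = tuple(self.roi_names)
        object.__setattr__(self, "roi_names", names)
        if len(set(names)) != len(names):
            raise ValueError("roi_names must be unique")
        if len(names) < 2:
            raise ValueError("a parcellation needs at least 2 ROIs")
        if self.vertex_assignment is not None:
            assignment = np.asarray(self.vertex_assignment, dtype=int)
            if assignment.ndim != 1:
                raise ValueError("vertex_assignment must be a 1-D index array")
            if assignment.size and (assignment.min() < 0 or assignment.max() >= len(names)):
                raise ValueError(
                    "vertex_assignment values must lie in "
                    f"[0, {len(names) - 1}]"
                )
            object.__setattr__(self, "vertex_assignment", assignment)

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    def index_of(self, name: str) -> int:
        try:
            return self.roi_names.index(name)
        except ValueError:
            raise KeyError(f"unknown ROI name: {name!r}") from None


def dk_parcellation(vertex_assignment: np.ndarray | None = None) -> ROIParcellation:
    """Return the shipped 35-region Desikan-Killiany parcellation."""
    return ROIParcellation(DK35_REGIONS, vertex_assignment)


def generic_parcellation(n_rois: int) -> ROIParcellation:
    """A synthetic parcellation with ``n_rois`` numbered regions (roi00, ...)."""
    width = max(2, len(str(n_rois - 1)))
    return ROIParcellation(tuple(f"roi{i:0{width}d}" for i in range(n_rois)))
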