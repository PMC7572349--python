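"""Graph-based infinite feature selection.

Features are nodes of a weighted graph whose adjacency mixes a dispersion
term with a decorrelation term:

    A(k, l) = alpha * max(sd_k, sd_l) + (1 - alpha) * (1 - |spearman(k, l)|)

A feature's relevance aggregates weighted walks of every length through that
graph; the infinite sum converges to the closed form

    S = (I - r A)^-1 - I,      score_k = [S e]_k  (row sums),

valid whenever the spectral radius of ``r A`` is below one.  Scores are
computed on training subjects only inside cross-validation, which is where
supervision enters; the scoring formula itself is label-free.

Scores are computed on the raw feature scale by default: the dispersion term
is where between-group mean separation shows up (a group shift inflates a
feature's pooled sd), so z-scoring — which pins every sd to 1 — would reduce
the adjacency to correlation structure only and erase that signal.
Standardization remains available (``standardize=True``) for bounded
adjacency entries; either way, divergence of the walk series
(spectral radius of r*A >= 1) raises instead of being hidden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


class InfsError(ValueError):
    pass


class InfsConvergenceError(InfsError):
    """Spectral radius of r*A is >= 1; the walk series diverges."""


@dataclass(frozen=True)
class InfsParams:
    """Knobs of the selection graph: loading alpha, damping r, z-scoring."""

    alpha: float = 0.5
    r: float = 0.01
    standardize: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise InfsError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.r <= 0:
            raise InfsError(f"r must be positive, got {self.r}")


@dataclass(frozen=True)
class FeatureRanking:
    """Per-feature relevance scores plus the induced deterministic ranking.

    ``ranks`` sorts features by non-increasing score, ties broken by
    ascending feature index.
    """

    scores: np.ndarray
    ranks: np.ndarray
    params: InfsParams = field(default_factory=InfsParams)

    @property
    def n_features(self) -> int:
        return self.scores.shape[0]

    def top(self, k: int) -> np.ndarray:
        if not (1 <= k <= self.n_features):
            raise InfsError(f"k must be in [1, {self.n_features}], got {k}")
        return self.ranks[:k]


def feature_adjacency(features: np.ndarray, params: InfsParams | None = None) -> np.ndarray:
    """Build the symmetric feature-relationship adjacency matrix.

    Requires at least 3 subjects (rank correlation is degenerate below
    that) and at least 2 features.  Constant features have undefined rank
    correlation; they get ``|rho| = 0`` (treated as uncorrelated) and are
    logged.
    """
    params = params or InfsParams()
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise InfsError("features must be a subjects x features matrix")
    n, n_f = X.shape
    if n < 3:
        raise InfsError(f"need at least 3 subjects for the adjacency, got {n}")
    if n_f < 2:
        raise InfsError(f"need at least 2 features, got {n_f}")
    if not np.all(np.isfinite(X)):
        raise InfsError("features contain non-finite values")

    sd = X.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "%d constant feature(s) at indices %s: sd=0, correlation undefined "
            "(treated as uncorrelated)",
            int(constant.sum()), np.flatnonzero(constant).tolist(),
        )
    if params.standardize:
        safe_sd = np.where(constant, 1.0, sd)
        X = (X - X.mean(axis=0)) / safe_sd
        sd = np.where(constant, 0.0, 1.0)

    # tie-corrected Spearman = Pearson correlation of mid-ranks
    ranks = rankdata(X, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.atleast_2d(rho)
    abs_rho = np.abs(rho)
    abs_rho[~np.isfinite(abs_rho)] = 0.0  # constant features: no correlation
    c = 1.0 - abs_rho
    np.fill_diagonal(c, 0.0)  # spearman(f, f) = 1

    sigma = np.maximum.outer(sd, sd)
    A = params.alpha * sigma + (1.0 - params.alpha) * c
    return (A + A.T) / 2.0


def infs_scores(A: np.ndarray, r: float = 0.01) -> np.ndarray:
    """Closed-form relevance scores: row sums of ``(I - r A)^-1 - I``.

    Raises :class:`InfsConvergenceError` when the spectral radius of ``r A``
    is >= 1; the remedy (lower r, or standardize features) is part of the
    message rather than applied silently.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise InfsError("adjacency must be square")
    if not np.all(np.isfinite(A)):
        raise InfsError("adjacency contains non-finite values")
    if not np.allclose(A, A.T, rtol=0.0, atol=1e-12):
        raise InfsError("adjacency must be symmetric")
    radius = float(np.max(np.abs(np.linalg.eigvalsh(A))))
    if r * radius >= 1.0:
        raise InfsConvergenceError(
            f"spectral radius of r*A is {r * radius:.4g} >= 1; the score series "
            "diverges — lower r or enable feature standardization"
        )
    n = A.shape[0]
    S = np.linalg.inv(np.eye(n) - r * A) - np.eye(n)
    return S.sum(axis=1)


def truncated_series_scores(A: np.ndarray, r: float, n_terms: int) -> np.ndarray:
    """Independent oracle: partial sum of ``sum_p r^p A^p e`` over p=1..n_terms."""
    A = np.asarray(A, dtype=float)
    e = np.ones(A.shape[0])
    total = np.zeros(A.shape[0])
    term = e.copy()
    for _ in range(n_terms):
        term = r * (A @ term)
        total += term
    return total


def rank_features(scores: np.ndarray, params: InfsParams | None = None) -> FeatureRanking:
    """Deterministic non-increasing ordering, ascending-index tie break."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1:
        raise InfsError("scores must be a 1-D vector")
    if not np.all(np.isfinite(scores)):
        raise InfsError("scores contain non-finite values")
    order = np.lexsort((np.arange(scores.shape[0]), -scores))
    return FeatureRanking(
        scores=scores, ranks=order, params=params or InfsParams()
    )


def score_features(features: np.ndarray, params: InfsParams | None = None) -> FeatureRanking:
    """Convenience: adjacency -> scores -> ranking in one call."""
    params = params or InfsParams()
    A = feature_adjacency(features, params)
    return rank_features(infs_scores(A, params.r), params)
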