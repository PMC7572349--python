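"""Cross-validated linear-SVM classification on top-K selected connections.

Every outer fold is self-contained: feature relevance is scored on the
training subjects only, the top-K connections are selected from that
training-fold ranking, the margin-cost hyperparameter is tuned by an inner
stratified 5-fold grid search on the training subjects, and only then is the
held-out fold predicted.  Held-out subjects never touch scaling statistics,
ranking, tuning or fitting.  Accuracy is pooled over all held-out
predictions (micro-average), which is also well-defined for leave-one-out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import warnings

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import LinearSVC

from .infs import FeatureRanking, InfsParams, rank_features, score_features

#: Log-spaced margin-cost grid for nested tuning.
COST_GRID: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3)


class CVError(ValueError):
    pass


@dataclass(frozen=True)
class CVScheme:
    """A cross-validation scheme: leave-one-out or (stratified) k-fold."""

    kind: str  # "loo" | "kfold"
    n_folds: int | None = None
    stratified: bool = True
    seed: int = 42

    def __post_init__(self) -> None:
        if self.kind not in ("loo", "kfold"):
            raise CVError(f"kind must be 'loo' or 'kfold', got {self.kind!r}")
        if self.kind == "kfold":
            if self.n_folds is None or self.n_folds < 2:
                raise CVError("kfold requires n_folds >= 2")

    @property
    def name(self) -> str:
        return "loo" if self.kind == "loo" else f"{self.n_folds}fold"

    def split(self, labels: np.ndarray) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        """Deterministic (train, test) index pairs for the given labels."""
        labels = np.asarray(labels)
        n = labels.shape[0]
        if self.kind == "loo":
            idx = np.arange(n)
            for i in range(n):
                yield np.delete(idx, i), np.array([i])
            return
        if self.n_folds > n:  # type: ignore[operator]
            raise CVError(f"n_folds={self.n_folds} exceeds n_subjects={n}")
        if self.stratified:
            counts = np.unique(labels, return_counts=True)[1]
            if counts.min() < self.n_folds:  # type: ignore[operator]
                raise CVError(
                    f"stratified {self.n_folds}-fold needs >= {self.n_folds} "
                    "subjects per class"
                )
            splitter = StratifiedKFold(
                n_splits=self.n_folds, shuffle=True, random_state=self.seed
            )
        else:
            splitter = KFold(n_splits=self.n_folds, shuffle=True, random_state=self.seed)
        yield from splitter.split(np.zeros((n, 1)), labels)


@dataclass
class FoldRecord:
    test_index: np.ndarray
    top_features: np.ndarray          # global feature indices, best first
    top_scores: np.ndarray            # their inFS scores on the training fold
    tuned_cost: float
    predictions: np.ndarray
    n_correct: int


@dataclass
class ClassificationResult:
    """Outcome of one (scheme, measurement, hemisphere) cross-validation run."""

    scheme: CVScheme
    measurement: str | None
    hemisphere: str | None
    accuracy: float
    folds: list[FoldRecord]
    fold_scores: np.ndarray | None  # n_folds x n_features inFS scores
    infs_params: InfsParams
    top_k: int

    @property
    def tuned_costs(self) -> list[float]:
        return [f.tuned_cost for f in self.folds]

    @property
    def n_heldout(self) -> int:
        return int(sum(f.test_index.size for f in self.folds))


def _check_two_classes(labels: np.ndarray, scheme: CVScheme) -> None:
    classes, counts = np.unique(labels, return_counts=True)
    if classes.shape[0] != 2:
        raise CVError(f"expected exactly 2 classes, found {classes.tolist()}")
    minimum = scheme.n_folds if (scheme.kind == "kfold" and scheme.stratified) else 2
    if counts.min() < minimum:  # type: ignore[operator]
        raise CVError(
            f"each class needs >= {minimum} subjects for scheme {scheme.name}"
        )


def _tune_cost(
    X: np.ndarray,
    y: np.ndarray,
    cost_grid: Sequence[float],
    inner_folds: int,
    seed: int,
) -> float:
    """Pick the cost maximizing inner stratified-CV accuracy (ties: smallest C)."""
    counts = np.unique(y, return_counts=True)[1]
    n_splits = int(min(inner_folds, counts.min()))
    if n_splits < 2:
        return float(cost_grid[len(cost_grid) // 2])
    splitter = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    splits = list(splitter.split(X, y))
    best_cost, best_correct = None, -1
    for cost in cost_grid:
        correct = 0
        for tr, te in splits:
            clf = _fit_svm(X[tr], y[tr], cost, seed)
            correct += int((clf.predict(X[te]) == y[te]).sum())
        if correct > best_correct:
            best_cost, best_correct = cost, correct
    return float(best_cost)


def _fit_svm(X: np.ndarray, y: np.ndarray, cost: float, seed: int) -> LinearSVC:
    """Linear max-margin fit via liblinear (iteration-capped, deterministic)."""
    clf = LinearSVC(C=cost, dual=True, random_state=seed, max_iter=1000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X, y)
    return clf


def _fit_scaler(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return mean, sd


def run_cv(
    features: np.ndarray,
    labels: np.ndarray,
    scheme: CVScheme,
    top_k: int = 100,
    infs_params: InfsParams | None = None,
    cost_grid: Sequence[float] = COST_GRID,
    inner_folds: int = 5,
    exclude_features: Sequence[int] | None = None,
    measurement: str | None = None,
    hemisphere: str | None = None,
    keep_fold_scores: bool = True,
) -> ClassificationResult:
    """Nested-CV classification with per-fold feature selection.

    ``exclude_features`` removes columns from both selection and training
    (used e.g. for leakage canaries); excluded columns report a zero score.
    """
    infs_params = infs_params or InfsParams()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise CVError("features and labels must align on subjects")
    n, n_f = X.shape
    selectable = np.arange(n_f)
    if exclude_features is not None:
        selectable = np.setdiff1d(selectable, np.asarray(exclude_features, dtype=int))
        if selectable.size == 0:
            raise CVError("all features excluded")
    if not (1 <= top_k <= selectable.size):
        raise CVError(
            f"top_k={top_k} must be in [1, {selectable.size}] (selectable features)"
        )
    _check_two_classes(y, scheme)

    folds: list[FoldRecord] = []
    all_scores: list[np.ndarray] = []
    correct_total = 0
    for train, test in scheme.split(y):
        y_train = y[train]
        if np.unique(y_train).shape[0] < 2:
            raise CVError(
                "single-class training fold encountered; use a stratified scheme"
            )
        ranking = score_features(X[np.ix_(train, selectable)], infs_params)
        top_local = ranking.top(top_k)
        top_global = selectable[top_local]

        full_scores = np.zeros(n_f)
        full_scores[selectable] = ranking.scores
        if keep_fold_scores:
            all_scores.append(full_scores)

        X_train = X[np.ix_(train, top_global)]
        X_test = X[np.ix_(test, top_global)]
        mean, sd = _fit_scaler(X_train)
        X_train = (X_train - mean) / sd
        X_test = (X_test - mean) / sd

        cost = _tune_cost(X_train, y_train, cost_grid, inner_folds, scheme.seed)
        clf = _fit_svm(X_train, y_train, cost, scheme.seed)
        pred = clf.predict(X_test)
        n_correct = int((pred == y[test]).sum())
        correct_total += n_correct
        folds.append(
            FoldRecord(
                test_index=np.asarray(test),
                top_features=top_global,
                top_scores=full_scores[top_global],
                tuned_cost=cost,
                predictions=pred,
                n_correct=n_correct,
            )
        )
    return ClassificationResult(
        scheme=scheme,
        measurement=measurement,
        hemisphere=hemisphere,
        accuracy=correct_total / n,
        folds=folds,
        fold_scores=np.vstack(all_scores) if keep_fold_scores else None,
        infs_params=infs_params,
        top_k=top_k,
    )


def scheme_feature_weights(
    features: np.ndarray,
    labels: np.ndarray,
    scheme: CVScheme,
    infs_params: InfsParams | None = None,
) -> np.ndarray:
    """Per-fold inFS scores of a scheme's selection stage, without classification.

    Returns an n_folds x n_features score matrix, identical to the
    ``fold_scores`` a full :func:`run_cv` would produce: the ranking is the
    same whether or not a classifier is trained afterwards.
    """
    infs_params = infs_params or InfsParams()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    _check_two_classes(y, scheme)
    rows = []
    for train, _test in scheme.split(y):
        if np.unique(y[train]).shape[0] < 2:
            raise CVError(
                "single-class training fold encountered; use a stratified scheme"
            )
        rows.append(score_features(X[train], infs_params).scores)
    return np.vstack(rows)


def accuracy_report(results: Sequence[ClassificationResult]) -> pd.DataFrame:
    """Per-(measurement, hemisphere) accuracies with the cross-scheme mean.

    Every (measurement, hemisphere) cell must carry every scheme appearing
    anywhere in ``results``; missing combinations are an error.
    """
    if not results:
        raise CVError("no results to report")
    schemes = sorted({r.scheme.name for r in results})
    cells: dict[tuple[str, str], dict[str, float]] = {}
    for r in results:
        key = (str(r.measurement), str(r.hemisphere))
        cells.setdefault(key, {})[r.scheme.name] = r.accuracy
    missing = [
        (meas, hemi, s)
        for (meas, hemi), accs in sorted(cells.items())
        for s in schemes
        if s not in accs
    ]
    if missing:
        raise CVError(f"missing scheme results for: {missing}")
    rows = []
    for (meas, hemi), accs in sorted(cells.items()):
        row = {"measurement": meas, "hemisphere": hemi}
        row.update({s: accs[s] for s in schemes})
        row["mean_accuracy"] = float(np.mean([accs[s] for s in schemes]))
        rows.append(row)
    return pd.DataFrame(rows)


def default_schemes(seed: int = 42) -> tuple[CVScheme, ...]:
    """The three schemes used throughout: LOO, stratified 5-fold and 10-fold."""
    return (
        CVScheme("loo", seed=seed),
        CVScheme("kfold", n_folds=5, seed=seed),
        CVScheme("kfold", n_folds=10, seed=seed),
    )
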