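"""Measurement layer: feature-selection scoring, separability and repeated CV.

This module turns a fitted projection into the quantities the benchmark
reports: the top-s selected features and their confusion counts against
a ground-truth manifest (with the precision = recall identity that holds
whenever exactly s features are selected), the cosine distance between a
fitted loading vector and the true one, the apparent (training-set)
separability of the first component, and the repeated stratified
cross-validated classification error.  All fitting statistics used in CV
(centering means, weights, centroids) are computed on the training folds
only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import clone

from .exceptions import InvalidInputError
from .extra_methods import ICA, RegularizedLDA, SparsePCA
from .methods import PCA, PLSDA, SparsePLSDA
from .synthetic import GroundTruthManifest

__all__ = [
    "CVConfig",
    "SelectionConfusion",
    "make_estimator",
    "rank_features",
    "select_top_features",
    "selection_confusion",
    "cosine_distance",
    "apparent_separability",
    "repeated_cv_error",
]


def make_estimator(
    method: str,
    n_components: int = 1,
    keep: int | None = None,
    seed: int = 0,
):
    """Build an estimator from its method tag.

    ``keep`` configures the support size of the sparse methods (ignored
    by the dense ones); ``seed`` only affects ICA's initialisation.
    """
    if method == "pca":
        return PCA(n_components=n_components)
    if method == "plsda":
        return PLSDA(n_components=n_components)
    if method == "splsda":
        return SparsePLSDA(n_components=n_components, keep=keep)
    if method == "ica":
        return ICA(n_components=n_components, random_state=seed)
    if method == "spca":
        return SparsePCA(n_components=n_components, keep=keep)
    if method == "rlda":
        return RegularizedLDA()
    raise InvalidInputError(f"unknown method tag {method!r}")


@dataclass
class SelectionConfusion:
    """Confusion counts of a selected feature set against the signal set."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0


@dataclass
class CVConfig:
    """Repeated stratified k-fold configuration."""

    folds: int = 5
    repetitions: int = 10
    ncomp: int = 1
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.folds < 2:
            raise InvalidInputError("need at least 2 folds")
        if self.repetitions < 1:
            raise InvalidInputError("need at least 1 repetition")


def rank_features(model, aggregate: str = "default") -> np.ndarray:
    """Full feature ranking by decreasing selection score.

    The default score is |weight| on the first component (each estimator
    may override, e.g. ICA uses the max over its components); pass
    ``aggregate='max'`` to force max-|weight| aggregation over all
    fitted components.  Ties are broken toward the lower feature index.
    """
    if aggregate == "default":
        scores = model.feature_scores()
    elif aggregate == "first":
        scores = np.abs(model.weights_[:, 0])
    elif aggregate == "max":
        scores = np.abs(model.weights_).max(axis=1)
    else:
        raise InvalidInputError(f"unknown aggregate {aggregate!r}")
    m = scores.shape[0]
    return np.lexsort((np.arange(m), -scores))


def select_top_features(model, s: int, aggregate: str = "default") -> np.ndarray:
    """Indices (sorted) of the s features with the largest selection scores."""
    ranking = rank_features(model, aggregate=aggregate)
    if not 1 <= s <= ranking.shape[0]:
        raise InvalidInputError(f"s must be in [1, {ranking.shape[0]}], got {s}")
    return np.sort(ranking[:s])


def selection_confusion(
    selected, truth: GroundTruthManifest, m: int
) -> SelectionConfusion:
    """Score a selected feature set against the manifest's signal set.

    When exactly s = |signal| features are selected, s = tp + fn and
    s = tp + fp, hence fp = fn and precision equals recall.
    """
    selected = np.asarray(sorted(set(int(i) for i in np.asarray(selected).ravel())))
    if selected.size and (selected.min() < 0 or selected.max() >= m):
        raise InvalidInputError("selected feature indices out of range")
    sel = np.zeros(m, dtype=bool)
    sel[selected] = True
    sig = np.zeros(m, dtype=bool)
    sig[np.asarray(truth.signal_indices, dtype=int)] = True
    tp = int(np.sum(sel & sig))
    fp = int(np.sum(sel & ~sig))
    fn = int(np.sum(~sel & sig))
    tn = int(np.sum(~sel & ~sig))
    return SelectionConfusion(tp=tp, fp=fp, fn=fn, tn=tn)


def cosine_distance(loading, truth_vector) -> float:
    """1 - |cos angle| between two vectors (sign-invariant, in [0, 1])."""
    u = np.asarray(loading, dtype=float).ravel()
    v = np.asarray(truth_vector, dtype=float).ravel()
    if u.shape != v.shape:
        raise InvalidInputError(f"length mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise InvalidInputError("cosine distance undefined for a zero vector")
    return float(np.clip(1.0 - abs(u @ v) / (nu * nv), 0.0, 1.0))


def apparent_separability(model, y) -> float:
    """Best training accuracy of a threshold on the first-component score.

    Scans every cut between distinct sorted score values (plus the two
    trivial cuts) in both orientations and returns the maximum accuracy,
    in [0.5, 1] for binary labels.  Equal scores cannot be separated by
    a threshold and are never split.
    """
    t = np.asarray(model.scores_[:, 0], dtype=float)
    y = np.asarray(y, dtype=int)
    n = t.shape[0]
    if y.shape[0] != n:
        raise InvalidInputError("labels do not match the number of fitted samples")
    order = np.argsort(t, kind="stable")
    ts, ys = t[order], y[order]
    ones_left = np.concatenate([[0], np.cumsum(ys)])  # ones among first k
    total_ones = ones_left[-1]
    k = np.arange(n + 1)
    zeros_left = k - ones_left
    # valid cut positions: between distinct values, plus the ends
    valid = np.ones(n + 1, dtype=bool)
    valid[1:n] = ts[1:] > ts[:-1]
    # orientation A: left -> class 0, right -> class 1
    acc_a = zeros_left + (total_ones - ones_left)
    # orientation B: left -> class 1, right -> class 0
    acc_b = ones_left + ((n - total_ones) - zeros_left)
    best = max(acc_a[valid].max(), acc_b[valid].max())
    return float(best) / n


def _stratified_folds(y: np.ndarray, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold assignment preserving class proportions; each class must have >= folds members."""
    assign = np.empty(y.shape[0], dtype=int)
    offset = 0
    for c in np.unique(y):
        idx = np.where(y == c)[0]
        if idx.size < folds:
            raise InvalidInputError(
                f"class {c} has {idx.size} samples, fewer than {folds} folds"
            )
        rng.shuffle(idx)
        assign[idx] = (np.arange(idx.size) + offset) % folds
        offset += idx.size
    return assign


def repeated_cv_error(method, X, y, cfg: CVConfig | None = None):
    """Mean held-out error of repeated k-fold CV, plus per-repetition errors.

    ``method`` is a method tag or an (unfitted) estimator to clone.  Each
    repetition draws a fresh fold assignment; within a fold the model is
    fitted on the training portion only and errors are counted on the
    held-out samples.  Returns ``(mean_error, per_repetition_errors)``.
    """
    cfg = cfg or CVConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = y.shape[0]
    if cfg.folds > n:
        raise InvalidInputError("more folds than samples")
    proto = make_estimator(method, n_components=cfg.ncomp) if isinstance(method, str) else method
    per_rep = np.empty(cfg.repetitions)
    for r in range(cfg.repetitions):
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), r]))
        for _resample in range(100):
            if cfg.stratified:
                assign = _stratified_folds(y, cfg.folds, rng)
            else:
                assign = rng.permutation(n) % cfg.folds
            ok = all(
                np.unique(y[assign != f]).size == 2 for f in range(cfg.folds)
            )
            if ok:
                break
        else:
            raise InvalidInputError("could not build folds with both classes in training")
        errors = 0
        for f in range(cfg.folds):
            train, test = assign != f, assign == f
            est = clone(proto)
            est.fit(X[train], y[train])
            errors += int(np.sum(est.predict(X[test]) != y[test]))
        per_rep[r] = errors / n
    return float(per_rep.mean()), per_rep
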