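"""Ground-truthed synthetic data generators.

Four data models, each emitting a :class:`LabeledDataset` whose manifest
names the signal features and the generating rule, so feature-selection
output can be scored against an exact ground truth:

``random_labels``
    i.i.d. U[0,1] features, fair-coin labels, empty signal set — the
    null model for curse-of-dimensionality experiments.
``linear``
    i.i.d. U[0,1] features; the label applies the linear rule
    "mean of the s signal features >= C -> class 0, else class 1"
    (threshold C = 0.5 sits at the median, giving near-balanced classes).
``cluster``
    signal features form two spherical Gaussian clusters (one per
    class); the center distance is set from a separation index
    ``sep`` in (-1, 1) via ``delta = 2 z_0.95 (1 + sep)/(1 - sep)`` in
    units of the cluster standard deviation; noise features are U[0,1].
``interval``
    constrained features are drawn from a fixed width-1/p subinterval of
    [0,1] (one subinterval per feature and class), all other features
    from U[0,1]; presets constrain either the class-1 signal features
    (``signal_constrained``) or additionally every noise feature
    (``noise_constrained``).

Signal features are generated in the leading columns and then scattered
by a recorded random column permutation, so their positions are
unpredictable but known to the manifest.  Every dataset is bit-exactly
reproducible from its :class:`GeneratorSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.stats import norm

from .exceptions import DegenerateInputError, InvalidInputError

__all__ = [
    "GeneratorSpec",
    "GroundTruthManifest",
    "LabeledDataset",
    "generate",
    "gen_random_labels",
    "gen_linear",
    "gen_cluster",
    "gen_interval",
    "true_loading_vector",
    "separation_to_distance",
    "distance_to_separation",
]

_MODELS = ("random_labels", "linear", "cluster", "interval")
_PRESETS = ("signal_constrained", "noise_constrained")
_Z95 = float(norm.ppf(0.95))
#: default within-cluster standard deviation: matches the sd of U[0,1] noise,
#: so only the cluster separation (not the marginal spread) carries class signal
DEFAULT_CLUSTER_SD = float(np.sqrt(1.0 / 12.0))
_MAX_RETRIES = 100


def separation_to_distance(sep: float, cluster_sd: float = DEFAULT_CLUSTER_SD) -> float:
    """Center distance realising separation index ``sep`` for two spherical
    clusters of standard deviation ``cluster_sd`` (quantile index, alpha=0.05)."""
    if not -1.0 < sep < 1.0:
        raise InvalidInputError(f"separation index must be in (-1, 1), got {sep}")
    return 2.0 * _Z95 * (1.0 + sep) / (1.0 - sep) * cluster_sd


def distance_to_separation(delta: float, cluster_sd: float = DEFAULT_CLUSTER_SD) -> float:
    """Inverse of :func:`separation_to_distance`."""
    r = delta / (2.0 * _Z95 * cluster_sd)
    return (r - 1.0) / (r + 1.0)


@dataclass(frozen=True)
class GeneratorSpec:
    """Full parameterization of one synthetic data model."""

    model: str
    n: int
    m: int
    s: int = 10
    C: float = 0.5
    sep: float = 0.0
    p: int = 3
    preset: str = "signal_constrained"
    interval_assignment: Mapping | None = None
    cluster_sd: float = DEFAULT_CLUSTER_SD
    noise_distribution: str = "uniform"
    seed: int = 0

    def __post_init__(self):
        if self.model not in _MODELS:
            raise InvalidInputError(f"unknown model {self.model!r}; expected one of {_MODELS}")
        if self.n < 4:
            raise InvalidInputError("need n >= 4 samples")
        if self.m < 1:
            raise InvalidInputError("need m >= 1 features")
        if not 0 <= self.s <= self.m:
            raise InvalidInputError(f"signal count s={self.s} must be in [0, m={self.m}]")
        if self.model in ("linear", "cluster", "interval") and self.s < 1:
            raise InvalidInputError(f"model {self.model!r} needs s >= 1")
        if not -0.9 <= self.sep <= 0.9:
            raise InvalidInputError(f"separation index must be in [-0.9, 0.9], got {self.sep}")
        if self.p < 1:
            raise InvalidInputError("subinterval divisor p must be >= 1")
        if not np.isfinite(self.C):
            raise InvalidInputError("rule constant C must be finite")
        if self.cluster_sd <= 0:
            raise InvalidInputError("cluster_sd must be positive")
        if self.interval_assignment is None and self.preset not in _PRESETS:
            raise InvalidInputError(f"unknown preset {self.preset!r}; expected one of {_PRESETS}")
        if self.noise_distribution != "uniform":
            raise InvalidInputError("only the uniform noise distribution is implemented")


@dataclass
class GroundTruthManifest:
    """Which features carry signal, and under what rule."""

    signal_indices: np.ndarray
    rule: dict
    true_loading: np.ndarray

    def to_dict(self) -> dict:
        rule = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.rule.items()
        }
        return {
            "signal_indices": np.asarray(self.signal_indices).tolist(),
            "rule": rule,
            "true_loading": np.asarray(self.true_loading).tolist(),
        }


@dataclass
class LabeledDataset:
    """An n x m feature matrix with binary labels and its ground-truth manifest."""

    X: np.ndarray
    y: np.ndarray
    truth: GroundTruthManifest
    spec: GeneratorSpec
    feature_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        n, m = self.X.shape
        if not self.feature_ids:
            self.feature_ids = [f"f{j:05d}" for j in range(m)]
        if not self.sample_ids:
            self.sample_ids = [f"s{i:05d}" for i in range(n)]


def true_loading_vector(truth: GroundTruthManifest) -> np.ndarray:
    """Unit-norm version of the manifest's true loading vector."""
    v = np.asarray(truth.true_loading, dtype=float)
    nv = np.linalg.norm(v)
    if nv == 0:
        raise InvalidInputError("manifest has an all-zero true loading (no signal features)")
    return v / nv


def _permute_columns(X: np.ndarray, s: int, rng: np.random.Generator):
    """Scatter the leading s signal columns; return permuted X, signal positions
    and the permutation (column j of the output is column perm[j] of the input)."""
    m = X.shape[1]
    perm = rng.permutation(m)
    signal = np.sort(np.where(perm < s)[0])
    return X[:, perm], signal, perm


def _finalize(X, y, spec, rule, signal, perm, loading_pre):
    loading = loading_pre[perm]
    rule = dict(rule)
    rule.update(model=spec.model, seed=spec.seed, column_permutation=perm)
    truth = GroundTruthManifest(
        signal_indices=signal, rule=rule, true_loading=loading
    )
    return LabeledDataset(X=X, y=y, truth=truth, spec=spec)


def _coin_labels(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 2, size=n)


def gen_random_labels(spec: GeneratorSpec) -> LabeledDataset:
    """Uniform noise in every feature, fair-coin labels, empty signal set."""
    if spec.model != "random_labels":
        raise InvalidInputError(f"spec.model is {spec.model!r}, expected 'random_labels'")
    for attempt in range(_MAX_RETRIES):
        rng = np.random.default_rng(spec.seed + attempt)
        X = rng.uniform(size=(spec.n, spec.m))
        y = _coin_labels(rng, spec.n)
        if min(np.sum(y == 0), np.sum(y == 1)) >= 2:
            break
    else:
        raise DegenerateInputError("could not draw both classes with >= 2 samples")
    perm = np.arange(spec.m)
    return _finalize(X, y, spec, {}, np.empty(0, dtype=int), perm, np.zeros(spec.m))


def gen_linear(spec: GeneratorSpec) -> LabeledDataset:
    """Linear class rule over the signal features.

    All features are i.i.d. U[0,1]; a sample is class 0 when the mean of
    its s signal features is >= C, class 1 otherwise (the sum-threshold
    rule read on the mean scale so C = 0.5 splits near the median).
    """
    if spec.model != "linear":
        raise InvalidInputError(f"spec.model is {spec.model!r}, expected 'linear'")
    degenerate_ok = spec.C <= 0.0 or spec.C >= 1.0  # rule is one-sided by construction
    for attempt in range(_MAX_RETRIES):
        rng = np.random.default_rng(spec.seed + attempt)
        X = rng.uniform(size=(spec.n, spec.m))
        y = (X[:, : spec.s].mean(axis=1) < spec.C).astype(int)
        if degenerate_ok or min(np.sum(y == 0), np.sum(y == 1)) >= 2:
            break
    else:
        raise DegenerateInputError(
            f"linear rule with C={spec.C} produced a degenerate labeling in "
            f"{_MAX_RETRIES} attempts"
        )
    Xp, signal, perm = _permute_columns(X, spec.s, rng)
    loading_pre = np.zeros(spec.m)
    loading_pre[: spec.s] = 1.0
    return _finalize(Xp, y, spec, {"C": spec.C, "s": spec.s}, signal, perm, loading_pre)


def gen_cluster(spec: GeneratorSpec) -> LabeledDataset:
    """Two Gaussian clusters in the signal subspace, uniform noise elsewhere.

    The clusters are spherical with standard deviation ``cluster_sd``
    and their centers sit ``separation_to_distance(sep)`` apart along a
    random direction of the signal subspace, centered on the noise mean
    of 0.5.  Class = cluster membership.
    """
    if spec.model != "cluster":
        raise InvalidInputError(f"spec.model is {spec.model!r}, expected 'cluster'")
    delta = separation_to_distance(spec.sep, spec.cluster_sd)
    for attempt in range(_MAX_RETRIES):
        rng = np.random.default_rng(spec.seed + attempt)
        y = _coin_labels(rng, spec.n)
        if min(np.sum(y == 0), np.sum(y == 1)) >= 2:
            break
    else:
        raise DegenerateInputError("could not draw both classes with >= 2 samples")
    u = rng.standard_normal(spec.s)
    u /= np.linalg.norm(u)
    centers = 0.5 + np.outer([-0.5, 0.5], delta * u)  # one row per class
    X = np.empty((spec.n, spec.m))
    X[:, : spec.s] = centers[y] + spec.cluster_sd * rng.standard_normal((spec.n, spec.s))
    X[:, spec.s :] = rng.uniform(size=(spec.n, spec.m - spec.s))
    Xp, signal, perm = _permute_columns(X, spec.s, rng)
    loading_pre = np.zeros(spec.m)
    loading_pre[: spec.s] = 1.0
    rule = {
        "sep": spec.sep,
        "cluster_sd": spec.cluster_sd,
        "center_distance": delta,
        "direction": u,  # aligned with pre-permutation signal columns 0..s-1
    }
    return _finalize(Xp, y, spec, rule, signal, perm, loading_pre)


def _resolve_assignment(spec: GeneratorSpec) -> dict:
    """Resolve the (class, feature-group) -> interval-kind map."""
    if spec.interval_assignment is not None:
        assignment = dict(spec.interval_assignment)
        for key, val in assignment.items():
            if (
                not isinstance(key, tuple)
                or len(key) != 2
                or key[0] not in (0, 1, "all")
                or key[1] not in ("signal", "noise")
            ):
                raise InvalidInputError(
                    f"unresolvable interval assignment key {key!r}; expected "
                    "(class 0|1|'all', 'signal'|'noise')"
                )
            if val not in ("subinterval", "full"):
                raise InvalidInputError(
                    f"interval assignment value must be 'subinterval' or 'full', got {val!r}"
                )
        return assignment
    if spec.preset == "signal_constrained":
        return {(1, "signal"): "subinterval"}
    # noise_constrained: every noise feature is low-variance for all samples,
    # class-1 signal features sit in their own subinterval
    return {("all", "noise"): "subinterval", (1, "signal"): "subinterval"}


def _interval_kind(assignment: dict, cls: int, group: str) -> tuple[str, bool]:
    """Return (kind, shared): shared=True when the 'all' scope applies, in which
    case both classes use the same subinterval (class-uninformative)."""
    if (cls, group) in assignment:
        return assignment[(cls, group)], False
    if ("all", group) in assignment:
        return assignment[("all", group)], True
    return "full", False


def gen_interval(spec: GeneratorSpec) -> LabeledDataset:
    """Interval-constrained features: values uniform on a width-1/p subinterval.

    For every (class, feature) pair the assignment decides whether values
    come from a fixed random subinterval [k/p, (k+1)/p] (k drawn once per
    class/feature, shared by all samples) or from the full [0,1].
    """
    if spec.model != "interval":
        raise InvalidInputError(f"spec.model is {spec.model!r}, expected 'interval'")
    assignment = _resolve_assignment(spec)
    for attempt in range(_MAX_RETRIES):
        rng = np.random.default_rng(spec.seed + attempt)
        y = _coin_labels(rng, spec.n)
        if min(np.sum(y == 0), np.sum(y == 1)) >= 2:
            break
    else:
        raise DegenerateInputError("could not draw both classes with >= 2 samples")
    # subinterval index per (class, feature); only used where constrained
    sub = rng.integers(0, spec.p, size=(2, spec.m))
    lows = np.zeros((2, spec.m))
    widths = np.ones((2, spec.m))
    for cls in (0, 1):
        for j in range(spec.m):
            group = "signal" if j < spec.s else "noise"
            kind, shared = _interval_kind(assignment, cls, group)
            if kind == "subinterval":
                k = sub[0, j] if shared else sub[cls, j]
                lows[cls, j] = k / spec.p
                widths[cls, j] = 1.0 / spec.p
    U = rng.uniform(size=(spec.n, spec.m))
    X = lows[y] + widths[y] * U
    Xp, signal, perm = _permute_columns(X, spec.s, rng)
    loading_pre = np.zeros(spec.m)
    loading_pre[: spec.s] = 1.0
    rule = {
        "p": spec.p,
        "preset": None if spec.interval_assignment is not None else spec.preset,
        "assignment": {f"{k[0]}:{k[1]}": v for k, v in assignment.items()},
        "subinterval_lows": lows,  # aligned with pre-permutation columns
        "subinterval_widths": widths,
    }
    return _finalize(Xp, y, spec, rule, signal, perm, loading_pre)


_DISPATCH = {
    "random_labels": gen_random_labels,
    "linear": gen_linear,
    "cluster": gen_cluster,
    "interval": gen_interval,
}


def generate(spec: GeneratorSpec) -> LabeledDataset:
    """Generate a dataset from any model tag."""
    return _DISPATCH[spec.model](spec)
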