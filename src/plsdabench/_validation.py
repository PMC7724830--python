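"""Input validation helpers shared by all estimators."""

from __future__ import annotations

import numpy as np

from .exceptions import InvalidInputError


def as_matrix(X, *, min_samples: int = 2) -> np.ndarray:
    """Coerce ``X`` to a finite 2-D float array with at least ``min_samples`` rows."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InvalidInputError(f"expected a 2-D samples x features matrix, got ndim={X.ndim}")
    n, m = X.shape
    if n < min_samples:
        raise InvalidInputError(f"need at least {min_samples} samples, got {n}")
    if m < 1:
        raise InvalidInputError("need at least one feature")
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("matrix contains NaN or infinite values")
    return X


def as_binary_labels(y, n_samples: int) -> np.ndarray:
    """Coerce ``y`` to an int vector of 0/1 labels with both classes present."""
    y = np.asarray(y)
    if y.ndim != 1 or y.shape[0] != n_samples:
        raise InvalidInputError(
            f"labels must be a length-{n_samples} vector, got shape {y.shape}"
        )
    y = y.astype(int)
    values = np.unique(y)
    if not np.all(np.isin(values, [0, 1])):
        raise InvalidInputError(f"labels must be in {{0, 1}}, got values {values}")
    if values.size < 2:
        raise InvalidInputError("both classes must be present for a supervised fit")
    return y


def check_n_components(d: int, n: int, m: int, *, what: str = "n_components") -> int:
    d = int(d)
    if d < 1:
        raise InvalidInputError(f"{what} must be >= 1, got {d}")
    dmax = min(n - 1, m)
    if d > dmax:
        raise InvalidInputError(
            f"{what}={d} exceeds min(n-1, m)={dmax} for an {n}x{m} matrix"
        )
    return d
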