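"""Core projection methods: PCA, PLS-DA and sparse PLS-DA.

All three estimators follow the scikit-learn protocol (``fit`` /
``transform`` / ``predict``, ``get_params`` / ``set_params``) but the
numerics are implemented here from first principles:

* :class:`PCA` diagonalises the sample covariance ``C = X'CnX/(n-1)``
  (via a thin SVD of the centered matrix, which is mathematically
  identical) and reports loading vectors ``L_i = sqrt(lambda_i) e_i``.
* :class:`PLSDA` extracts components ``a_h`` maximising the sample
  covariance ``cov(X_h a_h, y b_h)`` between projected features and the
  0/1 class labels.  For a single label column the covariance-driven
  eigenproblem is rank one, so each weight has the closed form
  ``a_h ∝ X_h' (y - mean(y))``; the data matrix is deflated between
  components (``y`` is not), which makes the score columns mutually
  orthogonal.
* :class:`SparsePLSDA` inserts a soft-thresholding step into the same
  iteration so that each weight column keeps an exact number of nonzero
  entries, turning the projection into an embedded feature selector.

Classification uses the nearest class centroid in score space; class
centroids are computed from the training scores, so unsupervised
projections (PCA) can also act as classifier front-ends when labels are
passed to ``fit``.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from ._validation import as_binary_labels, as_matrix, check_n_components
from .exceptions import DegenerateInputError, InvalidInputError

__all__ = [
    "PCA",
    "PLSDA",
    "SparsePLSDA",
    "center",
    "pca_fit",
    "plsda_fit",
    "splsda_fit",
    "predict",
    "soft_threshold_keep",
]

_VAR_TOL = 1e-12


def center(X):
    """Column-center ``X`` (equivalent to the action of the centering matrix Cn).

    Returns ``(X_centered, column_means)``.  Idempotent: centering a
    centered matrix changes nothing.
    """
    X = as_matrix(X)
    means = X.mean(axis=0)
    return X - means, means


def _fix_sign(w: np.ndarray) -> float:
    """Sign convention: the largest-magnitude entry of a weight column is positive.

    Returns the multiplier (+1 or -1) applied by the caller to every
    quantity tied to the component's orientation.
    """
    j = int(np.argmax(np.abs(w)))
    return -1.0 if w[j] < 0 else 1.0


def soft_threshold_keep(w: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold ``w`` so exactly ``keep`` largest-|.| entries survive.

    The threshold is the largest excluded magnitude, i.e. the classic
    lasso/soft-thresholding operator with the penalty chosen to hit an
    exact support size.  Ties are broken toward lower feature indices;
    a kept entry whose magnitude equals the threshold is clamped to the
    smallest positive float so the support-size contract holds.
    """
    w = np.asarray(w, dtype=float)
    m = w.shape[0]
    if not 1 <= keep <= m:
        raise InvalidInputError(f"keep must be in [1, {m}], got {keep}")
    if keep == m:
        return w.copy()
    mag = np.abs(w)
    order = np.lexsort((np.arange(m), -mag))
    kept = order[:keep]
    thr = mag[order[keep]]
    out = np.zeros_like(w)
    shrunk = np.maximum(mag[kept] - thr, np.finfo(float).tiny)
    out[kept] = np.sign(w[kept]) * shrunk
    return out


class _ScoreSpaceModel(BaseEstimator):
    """Shared plumbing: centering, projection to score space, centroid prediction.

    Fitted attributes common to every method
    ----------------------------------------
    weights_ : (m, d) unit-norm direction per component
    loadings_ : (m, d) loading vectors
    scores_ : (n, d) training scores
    component_importance_ : (d,) eigenvalue / covariance objective per component
    mean_ : (m,) centering means
    classes_, centroids_ : set when labels were available at fit time
    """

    method: str = ""

    def _projection_matrix(self) -> np.ndarray:
        return self.weights_

    def _check_fitted(self):
        if not hasattr(self, "weights_"):
            raise NotFittedError(f"this {type(self).__name__} instance is not fitted yet")

    def _fit_centroids(self, y: np.ndarray):
        self.classes_ = np.unique(y)
        self.centroids_ = np.vstack(
            [self.scores_[y == c].mean(axis=0) for c in self.classes_]
        )

    def transform(self, X) -> np.ndarray:
        """Project new samples onto the fitted components (score space)."""
        self._check_fitted()
        X = as_matrix(X, min_samples=1)
        if X.shape[1] != self.mean_.shape[0]:
            raise InvalidInputError(
                f"feature-count mismatch: model has {self.mean_.shape[0]}, input has {X.shape[1]}"
            )
        return (X - self.mean_) @ self._projection_matrix()

    def fit_transform(self, X, y=None) -> np.ndarray:
        self.fit(X, y)
        return self.scores_

    def predict(self, X) -> np.ndarray:
        """Assign each sample to the class of the nearest training centroid in score space."""
        self._check_fitted()
        if not hasattr(self, "centroids_"):
            raise NotFittedError(
                "no class centroids available; fit with labels to enable prediction"
            )
        T = self.transform(X)
        d2 = ((T[:, None, :] - self.centroids_[None, :, :]) ** 2).sum(axis=2)
        return self.classes_[np.argmin(d2, axis=1)]

    def feature_scores(self) -> np.ndarray:
        """Per-feature selection scores: |weight| on the first component."""
        self._check_fitted()
        return np.abs(self.weights_[:, 0])


class PCA(_ScoreSpaceModel):
    """Principal component analysis via the covariance eigenproblem.

    Components are the leading eigenvectors of ``C = X'CnX/(n-1)``;
    ``component_importance_`` holds the eigenvalues in non-increasing
    order and ``loadings_`` the eigenvalue-scaled eigenvectors
    ``sqrt(lambda_i) e_i``.

    Parameters
    ----------
    n_components : int
        Number of components, at most ``min(n - 1, m)``.
    """

    method = "pca"

    def __init__(self, n_components: int = 1):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = as_matrix(X)
        n, m = X.shape
        d = check_n_components(self.n_components, n, m)
        Xc, self.mean_ = center(X)
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        eigvals = S**2 / (n - 1)
        if eigvals[0] <= _VAR_TOL:
            raise DegenerateInputError("matrix has (numerically) zero variance")
        W = Vt[:d].T.copy()
        for h in range(d):
            W[:, h] *= _fix_sign(W[:, h])
        self.weights_ = W
        self.component_importance_ = eigvals[:d]
        self.loadings_ = W * np.sqrt(np.maximum(eigvals[:d], 0.0))
        self.scores_ = Xc @ W
        self.n_features_in_ = m
        if y is not None:
            self._fit_centroids(as_binary_labels(y, n))
        return self


class PLSDA(_ScoreSpaceModel):
    """Partial least-squares discriminant analysis (single 0/1 label column).

    Each component maximises ``cov(X_h a_h, y b_h)`` over unit-norm
    ``a_h``; because the label block is a single column the solution is
    the closed form ``a_h ∝ X_h'(y - mean(y))``.  ``X`` is deflated by
    the rank-one score/loading update between components (``y`` is not
    deflated), giving mutually orthogonal score columns.  New data are
    projected with the rotation matrix ``W (P'W)^{-1}`` so that
    ``transform(X_train)`` reproduces the training scores exactly.
    """

    method = "plsda"

    def __init__(self, n_components: int = 1):
        self.n_components = n_components

    def _component_weight(self, w_raw: np.ndarray, h: int) -> np.ndarray:
        return w_raw

    def fit(self, X, y):
        X = as_matrix(X)
        n, m = X.shape
        y = as_binary_labels(y, n)
        d = int(self.n_components)
        if d < 1:
            raise InvalidInputError(f"n_components must be >= 1, got {d}")
        dmax = min(n - 1, m)
        if d > dmax:
            warnings.warn(
                f"n_components={d} exceeds min(n-1, m)={dmax}; truncating", stacklevel=2
            )
            d = dmax

        Xc, self.mean_ = center(X)
        yc = y - y.mean()
        Xh = Xc.copy()
        Ws, Ts, Ps, Bs, imps = [], [], [], [], []
        for h in range(d):
            w = self._component_weight(Xh.T @ yc, h)
            nw = np.linalg.norm(w)
            if nw <= 1e-12 * max(1.0, np.abs(Xh).max()):
                warnings.warn(
                    f"component {h + 1}: residual covariance is zero; "
                    f"truncating to {h} components",
                    stacklevel=2,
                )
                break
            w = w / nw
            t = Xh @ w
            tt = float(t @ t)
            if tt <= _VAR_TOL:
                warnings.warn(
                    f"component {h + 1}: zero score variance; truncating", stacklevel=2
                )
                break
            sign = _fix_sign(w)
            w, t = sign * w, sign * t
            p = Xh.T @ t / tt
            b = float(yc @ t) / tt
            Xh = Xh - np.outer(t, p)
            Ws.append(w)
            Ts.append(t)
            Ps.append(p)
            Bs.append(b)
            imps.append(abs(float(t @ yc)) / (n - 1))
        if not Ws:
            raise DegenerateInputError("no informative PLS component could be extracted")
        W = np.column_stack(Ws)
        P = np.column_stack(Ps)
        self.weights_ = W
        self.loadings_ = W
        self.x_loadings_ = P
        self.y_loadings_ = np.asarray(Bs)
        self.component_importance_ = np.asarray(imps)
        self.scores_ = np.column_stack(Ts)
        # rotation so that (X - mean) @ rotations_ equals the deflation scores
        self.rotations_ = W @ np.linalg.inv(P.T @ W)
        self.n_features_in_ = m
        self._fit_centroids(y)
        return self

    def _projection_matrix(self) -> np.ndarray:
        return self.rotations_


class SparsePLSDA(PLSDA):
    """Sparse PLS-DA: PLS-DA weights soft-thresholded to an exact support size.

    Parameters
    ----------
    n_components : int
    keep : int or sequence of int
        Number of nonzero entries in each component's weight vector
        (one value broadcast to all components, or one per component).
        ``keep = m`` reproduces plain PLS-DA.
    """

    method = "splsda"

    def __init__(self, n_components: int = 1, keep: int | None = None):
        super().__init__(n_components=n_components)
        self.keep = keep

    def _keep_for(self, h: int, m: int) -> int:
        keep = self.keep
        if keep is None:
            return m
        if np.isscalar(keep):
            return int(keep)
        keep = list(keep)
        if len(keep) <= h:
            raise InvalidInputError(
                f"keep sequence of length {len(keep)} is shorter than n_components"
            )
        return int(keep[h])

    def _component_weight(self, w_raw: np.ndarray, h: int) -> np.ndarray:
        return soft_threshold_keep(w_raw, self._keep_for(h, w_raw.shape[0]))


def pca_fit(X, d: int) -> PCA:
    """Functional wrapper: fit a :class:`PCA` with ``d`` components."""
    return PCA(n_components=d).fit(X)


def plsda_fit(X, y, d: int) -> PLSDA:
    """Functional wrapper: fit a :class:`PLSDA` with ``d`` components."""
    return PLSDA(n_components=d).fit(X, y)


def splsda_fit(X, y, d: int, keep) -> SparsePLSDA:
    """Functional wrapper: fit a :class:`SparsePLSDA` (``keep`` nonzeros per component)."""
    return SparsePLSDA(n_components=d, keep=keep).fit(X, y)


def predict(model: _ScoreSpaceModel, X_new) -> np.ndarray:
    """Functional wrapper for nearest-centroid class prediction in score space."""
    return model.predict(X_new)
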