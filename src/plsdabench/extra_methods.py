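"""Comparison methods: FastICA, sparse PCA via regularized SVD, regularized LDA.

These expose the same fitted surface as the core projections
(``weights_``, ``scores_``, ``component_importance_``, centroid
``predict``) so they are interchangeable in every evaluation and
experiment routine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve

from ._validation import as_binary_labels, as_matrix, check_n_components
from .exceptions import DegenerateInputError, InvalidInputError, SingularScatterError
from .methods import _VAR_TOL, _ScoreSpaceModel, _fix_sign, center, soft_threshold_keep

__all__ = [
    "ICA",
    "SparsePCA",
    "RegularizedLDA",
    "RegularizationConfig",
    "ica_fit",
    "spca_fit",
    "rlda_fit",
]

# E[log cosh(Z)] for standard normal Z, used by the negentropy approximation
_GAUSS_LOGCOSH = 0.374567207491438


@dataclass
class RegularizationConfig:
    """Hyper-parameters for the comparison methods.

    ridge : L2 strength for RLDA; ``None`` selects a scale-free default
        of 1e-3 times the mean diagonal of the within-class scatter.
    spca_keep : nonzero count per SPCA component (``None`` = dense).
    ica_tol, ica_max_iter : FastICA fixed-point convergence controls.
    """

    ridge: float | None = None
    spca_keep: int | None = None
    ica_tol: float = 1e-6
    ica_max_iter: int = 500

    def __post_init__(self):
        if self.ridge is not None and self.ridge < 0:
            raise InvalidInputError("ridge must be non-negative")
        if self.ica_max_iter < 1:
            raise InvalidInputError("ica_max_iter must be >= 1")


def _sym_decorrelation(W: np.ndarray) -> np.ndarray:
    """W <- (W W')^{-1/2} W, the symmetric orthogonalisation of FastICA."""
    vals, vecs = np.linalg.eigh(W @ W.T)
    vals = np.maximum(vals, 1e-18)
    return (vecs / np.sqrt(vals)) @ vecs.T @ W


class ICA(_ScoreSpaceModel):
    """Independent component analysis (fixed-point negentropy maximisation).

    The data are whitened by PCA, then the unmixing matrix is driven to a
    fixed point of the log-cosh contrast with symmetric decorrelation.
    Components are ordered by decreasing negentropy approximation
    ``(E[log cosh s] - E[log cosh Z])^2``.  Deterministic given
    ``random_state``.  If the iteration does not converge within
    ``max_iter`` sweeps, the best iterate is returned and ``converged_``
    is False.
    """

    method = "ica"

    def __init__(
        self,
        n_components: int = 1,
        tol: float = 1e-6,
        max_iter: int = 500,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = as_matrix(X)
        n, m = X.shape
        d = check_n_components(self.n_components, n, m)
        Xc, self.mean_ = center(X)
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        if S[0] ** 2 / (n - 1) <= _VAR_TOL:
            raise DegenerateInputError("matrix has (numerically) zero variance")
        # whitening map K: (X - mean) @ K has identity covariance in d dims
        K = Vt[:d].T / S[:d] * np.sqrt(n - 1)
        Z = Xc @ K

        rng = np.random.default_rng(self.random_state)
        W = _sym_decorrelation(rng.standard_normal((d, d)))
        self.converged_ = False
        for _ in range(int(self.max_iter)):
            G = np.tanh(Z @ W.T)
            g_prime = (1.0 - G**2).mean(axis=0)
            W_new = _sym_decorrelation(G.T @ Z / n - g_prime[:, None] * W)
            delta = float(np.max(np.abs(np.abs(np.einsum("ij,ij->i", W_new, W)) - 1.0)))
            W = W_new
            if delta < self.tol:
                self.converged_ = True
                break

        sources = Z @ W.T  # unit-variance independent sources
        negentropy = (np.log(np.cosh(sources)).mean(axis=0) - _GAUSS_LOGCOSH) ** 2
        order = np.argsort(-negentropy, kind="stable")
        M = (K @ W.T)[:, order]  # feature-space unmixing directions
        norms = np.linalg.norm(M, axis=0)
        norms[norms == 0] = 1.0
        Wf = M / norms
        for h in range(d):
            Wf[:, h] *= _fix_sign(Wf[:, h])
        self.weights_ = Wf
        self.loadings_ = Wf
        self.unmixing_ = Wf.T
        self.component_importance_ = negentropy[order]
        self.scores_ = Xc @ Wf
        self.n_features_in_ = m
        if y is not None:
            self._fit_centroids(as_binary_labels(y, n))
        return self

    def feature_scores(self) -> np.ndarray:
        """ICA ranks features by their maximum |unmixing weight| over components."""
        self._check_fitted()
        return np.abs(self.weights_).max(axis=1)


class SparsePCA(_ScoreSpaceModel):
    """Sparse PCA via alternating regularized SVD.

    Each component alternates the rank-one SVD updates ``u <- Xv/|Xv|``,
    ``v <- soft-threshold(X'u)`` until the right vector stabilises, then
    the matrix is deflated by the fitted rank-one part.  With
    ``keep=None`` the thresholding is inactive and the directions
    coincide with plain PCA.
    """

    method = "spca"

    def __init__(
        self,
        n_components: int = 1,
        keep: int | None = None,
        max_iter: int = 200,
        tol: float = 1e-10,
    ):
        self.n_components = n_components
        self.keep = keep
        self.max_iter = max_iter
        self.tol = tol

    def _keep_for(self, h: int, m: int) -> int | None:
        keep = self.keep
        if keep is None:
            return None
        if np.isscalar(keep):
            return int(keep)
        keep = list(keep)
        if len(keep) <= h:
            raise InvalidInputError(
                f"keep sequence of length {len(keep)} is shorter than n_components"
            )
        return int(keep[h])

    def fit(self, X, y=None):
        X = as_matrix(X)
        n, m = X.shape
        d = check_n_components(self.n_components, n, m)
        Xc, self.mean_ = center(X)
        if np.max(Xc.var(axis=0)) <= _VAR_TOL:
            raise DegenerateInputError("matrix has (numerically) zero variance")
        Xh = Xc.copy()
        Ws, Ts, imps = [], [], []
        for h in range(d):
            _, _, Vt = np.linalg.svd(Xh, full_matrices=False)
            v = Vt[0]
            keep = self._keep_for(h, m)
            for _ in range(int(self.max_iter)):
                Xv = Xh @ v
                nu = np.linalg.norm(Xv)
                if nu <= 1e-15:
                    break
                u = Xv / nu
                w = Xh.T @ u
                if keep is not None:
                    w = soft_threshold_keep(w, keep)
                nv = np.linalg.norm(w)
                if nv <= 1e-15:
                    break
                v_new = w / nv
                if min(
                    np.linalg.norm(v_new - v), np.linalg.norm(v_new + v)
                ) < self.tol:
                    v = v_new
                    break
                v = v_new
            v = v * _fix_sign(v)
            t = Xh @ v
            Ws.append(v)
            Ts.append(t)
            imps.append(float(t @ t) / (n - 1))
            Xh = Xh - np.outer(t, v)
        W = np.column_stack(Ws)
        self.weights_ = W
        self.component_importance_ = np.asarray(imps)
        self.loadings_ = W * np.sqrt(np.maximum(self.component_importance_, 0.0))
        self.scores_ = np.column_stack(Ts)
        self.n_features_in_ = m
        if y is not None:
            self._fit_centroids(as_binary_labels(y, n))
        return self


class RegularizedLDA(_ScoreSpaceModel):
    """Fisher discriminant with an L2-stabilised within-class scatter.

    The single discriminant direction is
    ``w ∝ (S_W + ridge I)^{-1} (mu_1 - mu_0)`` with ``S_W`` the pooled
    within-class covariance.  ``ridge=None`` uses 1e-3 times the mean
    diagonal of ``S_W`` (scale-free); ``ridge=0`` requires ``S_W`` to be
    positive definite and raises :class:`SingularScatterError` otherwise.
    """

    method = "rlda"

    def __init__(self, ridge: float | None = None):
        self.ridge = ridge

    def fit(self, X, y):
        X = as_matrix(X)
        n, m = X.shape
        y = as_binary_labels(y, n)
        Xc, self.mean_ = center(X)
        mu = {c: X[y == c].mean(axis=0) for c in (0, 1)}
        Sw = np.zeros((m, m))
        for c in (0, 1):
            R = X[y == c] - mu[c]
            Sw += R.T @ R
        Sw /= max(n - 2, 1)

        ridge = self.ridge
        if ridge is None:
            ridge = 1e-3 * float(np.mean(np.diag(Sw)))
        if ridge < 0:
            raise InvalidInputError("ridge must be non-negative")
        A = Sw + ridge * np.eye(m)
        diff = mu[1] - mu[0]
        try:
            w = cho_solve(cho_factor(A), diff)
        except LinAlgError as err:
            raise SingularScatterError(
                "within-class scatter is singular; use a positive ridge"
            ) from err
        nw = np.linalg.norm(w)
        if nw <= 1e-15:
            raise DegenerateInputError("class means coincide; no discriminant direction")
        w = w / nw
        w = w * _fix_sign(w)
        self.ridge_ = float(ridge)
        self.weights_ = w[:, None]
        self.loadings_ = self.weights_
        denom = float(w @ Sw @ w)
        fisher = float(w @ diff) ** 2 / denom if denom > 0 else np.inf
        self.component_importance_ = np.asarray([fisher])
        self.scores_ = Xc @ self.weights_
        self.n_features_in_ = m
        self._fit_centroids(y)
        return self


def ica_fit(X, d: int, cfg: RegularizationConfig | None = None, seed: int = 0) -> ICA:
    cfg = cfg or RegularizationConfig()
    return ICA(
        n_components=d, tol=cfg.ica_tol, max_iter=cfg.ica_max_iter, random_state=seed
    ).fit(X)


def spca_fit(X, d: int, cfg: RegularizationConfig | None = None) -> SparsePCA:
    cfg = cfg or RegularizationConfig()
    return SparsePCA(n_components=d, keep=cfg.spca_keep).fit(X)


def rlda_fit(X, y, cfg: RegularizationConfig | None = None) -> RegularizedLDA:
    cfg = cfg or RegularizationConfig()
    return RegularizedLDA(ridge=cfg.ridge).fit(X, y)
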