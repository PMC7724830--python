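"""Core projection methods: centering, PCA, PLS-DA, sparse PLS-DA, prediction."""

import numpy as np
import pytest

from plsdabench import PCA, PLSDA, SparsePLSDA, center, pca_fit, plsda_fit, splsda_fit
from plsdabench.exceptions import DegenerateInputError, InvalidInputError
from plsdabench.methods import soft_threshold_keep


def explicit_covariance(X):
    """Oracle: form C = X' Cn X / (n-1) with the centering matrix materialized."""
    n = X.shape[0]
    Cn = np.eye(n) - np.ones((n, n)) / n
    return X.T @ Cn @ X / (n - 1)


def explicit_label_covariance(X, y):
    """Oracle: form C = X' Cn y y' Cn X / (n-1)^2 explicitly."""
    n = X.shape[0]
    Cn = np.eye(n) - np.ones((n, n)) / n
    v = Cn @ y.astype(float)
    return X.T @ np.outer(v, v) @ X / (n - 1) ** 2


class TestCenter:
    def test_small_example(self):
        Xc, means = center([[1.0, 2.0], [3.0, 4.0]])
        np.testing.assert_allclose(Xc, [[-1, -1], [1, 1]])
        np.testing.assert_allclose(means, [2, 3])

    def test_idempotent_and_constant_column(self, rng):
        X = rng.normal(size=(4, 3))
        Xc, _ = center(X)
        Xcc, _ = center(Xc)
        np.testing.assert_allclose(Xcc, Xc, atol=1e-14)
        Xc2, _ = center(np.array([[5.0], [5.0], [5.0]]))
        np.testing.assert_allclose(Xc2, 0.0)

    def test_rejects_single_sample(self):
        with pytest.raises(InvalidInputError):
            center([[1.0, 2.0]])


class TestPCA:
    def test_symmetric_diagonal(self):
        X = np.array([[-1.0, -1.0], [0.0, 0.0], [1.0, 1.0]])
        model = pca_fit(X, 1)
        np.testing.assert_allclose(
            np.abs(model.weights_[:, 0]), [1 / np.sqrt(2)] * 2, atol=1e-12
        )

    def test_eigenvalues_match_dense_eigensolver(self, rng):
        X = rng.normal(size=(6, 4))
        model = pca_fit(X, 4)
        vals = np.sort(np.linalg.eigvalsh(explicit_covariance(X)))[::-1]
        np.testing.assert_allclose(model.component_importance_, vals[:4], atol=1e-10)

    def test_loading_scaling(self, rng):
        # loadings are sqrt(eigenvalue)-scaled eigenvectors
        X = rng.normal(size=(30, 5))
        model = pca_fit(X, 3)
        np.testing.assert_allclose(
            model.loadings_,
            model.weights_ * np.sqrt(model.component_importance_),
            atol=1e-12,
        )
        # unit case: eigenvalue 4 with axis-aligned eigenvector gives loading 2
        # sum of squares 12 over n - 1 = 3 samples gives eigenvalue 4
        t = np.array([-3.0, -1.0, 1.0, 3.0]) * np.sqrt(12.0 / 20.0)
        X2 = np.column_stack([t, np.zeros(4)])
        m2 = pca_fit(X2, 1)
        np.testing.assert_allclose(m2.component_importance_[0], 4.0, atol=1e-12)
        np.testing.assert_allclose(np.abs(m2.loadings_[:, 0]), [2.0, 0.0], atol=1e-10)

    def test_variance_conservation_and_orthonormality(self, rng):
        X = rng.normal(size=(20, 7))
        d = min(19, 7)
        model = pca_fit(X, d)
        total = np.trace(explicit_covariance(X))
        assert abs(model.component_importance_.sum() - total) / total < 1e-8
        np.testing.assert_allclose(
            model.weights_.T @ model.weights_, np.eye(d), atol=1e-8
        )
        # importances non-increasing
        assert np.all(np.diff(model.component_importance_) <= 1e-12)

    def test_invalid_inputs(self, rng):
        with pytest.raises(InvalidInputError):
            pca_fit(rng.normal(size=(5, 3)), 5)  # d > min(n-1, m)
        with pytest.raises(DegenerateInputError):
            pca_fit(np.ones((4, 3)), 1)  # zero variance


class TestPLSDA:
    def test_first_weight_is_label_covariance_direction(self, rng):
        X = rng.normal(size=(8, 5))
        y = np.array([0, 1, 0, 1, 1, 0, 1, 0])
        model = plsda_fit(X, y, 1)
        # oracle: sole nontrivial eigenvector of the rank-one label covariance
        vals, vecs = np.linalg.eigh(explicit_label_covariance(X, y))
        e = vecs[:, -1]
        w = model.weights_[:, 0]
        assert min(np.abs(w - e).max(), np.abs(w + e).max()) < 1e-10

    def test_perfect_feature_dominates_first_weight(self, rng):
        n = 200
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
        X = rng.normal(size=(n, 10))
        X[:, 3] = y - y.mean()
        model = plsda_fit(X, y, 1)
        assert np.argmax(np.abs(model.weights_[:, 0])) == 3

    def test_supervised_direction_differs_from_variance_direction(self, rng):
        # dominant variance along u, class split along v perpendicular to u
        n = 400
        u, v = np.array([1.0, 1.0]) / np.sqrt(2), np.array([1.0, -1.0]) / np.sqrt(2)
        y = rng.integers(0, 2, n)
        X = (
            np.outer(rng.normal(scale=5.0, size=n), u)
            + np.outer(2 * y - 1 + 0.3 * rng.normal(size=n), v)
        )
        wp = pca_fit(X, 1).weights_[:, 0]
        wl = plsda_fit(X, y, 1).weights_[:, 0]
        angle = np.degrees(np.arccos(min(1.0, abs(wp @ wl))))
        assert angle > 45.0

    def test_scores_orthogonal_and_deflation_monotone(self, rng):
        X = rng.normal(size=(30, 8))
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        model = plsda_fit(X, y, 4)
        G = model.scores_.T @ model.scores_
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-8)
        # deflation strictly reduces the Frobenius norm component by component
        Xc = X - X.mean(axis=0)
        norms = [np.linalg.norm(Xc)]
        Xh = Xc.copy()
        for h in range(4):
            t = model.scores_[:, h]
            p = Xh.T @ t / (t @ t)
            Xh = Xh - np.outer(t, p)
            norms.append(np.linalg.norm(Xh))
        assert all(b < a for a, b in zip(norms, norms[1:]))

    def test_transform_reproduces_training_scores(self, rng):
        X = rng.normal(size=(25, 6))
        y = rng.integers(0, 2, 25)
        y[:2] = [0, 1]
        model = plsda_fit(X, y, 3)
        np.testing.assert_allclose(model.transform(X), model.scores_, atol=1e-10)

    def test_single_class_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            plsda_fit(rng.normal(size=(10, 3)), np.zeros(10, dtype=int), 1)

    def test_excessive_components_truncated_with_warning(self, rng):
        X = rng.normal(size=(6, 3))
        y = np.array([0, 1, 0, 1, 0, 1])
        with pytest.warns(UserWarning):
            model = PLSDA(n_components=10).fit(X, y)
        assert model.weights_.shape[1] <= 3


class TestSparsePLSDA:
    def test_full_keep_equals_plsda(self, rng):
        X = rng.normal(size=(40, 12))
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        dense = plsda_fit(X, y, 3)
        sparse = splsda_fit(X, y, 3, keep=12)
        np.testing.assert_allclose(sparse.weights_, dense.weights_, atol=1e-10)

    def test_keep_one_matches_exhaustive_covariance_search(self, rng):
        X = rng.uniform(size=(60, 9))
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        model = splsda_fit(X, y, 1, keep=1)
        support = np.nonzero(model.weights_[:, 0])[0]
        yc = y - y.mean()
        brute = np.argmax(np.abs((X - X.mean(axis=0)).T @ yc))
        assert list(support) == [brute]

    @pytest.mark.parametrize("keep", [1, 3, 7, 12])
    def test_exact_support_size(self, rng, keep):
        X = rng.normal(size=(30, 12))
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        model = splsda_fit(X, y, 2, keep=keep)
        for h in range(model.weights_.shape[1]):
            assert np.count_nonzero(model.weights_[:, h]) == keep

    def test_keep_out_of_range(self, rng):
        X = rng.normal(size=(10, 4))
        y = np.array([0, 1] * 5)
        with pytest.raises(InvalidInputError):
            splsda_fit(X, y, 1, keep=5)

    def test_threshold_operator_survivors(self):
        w = np.array([0.9, -0.5, 0.1, 0.0, -1.2])
        out = soft_threshold_keep(w, 2)
        assert set(np.nonzero(out)[0]) == {0, 4}
        # surviving magnitudes are shrunk by the largest excluded one
        np.testing.assert_allclose(out[[0, 4]], [0.4, -0.7], atol=1e-12)


class TestPredict:
    def test_training_error_zero_on_separated_clusters(self, cluster_data):
        model = plsda_fit(cluster_data.X, cluster_data.y, 1)
        assert np.mean(model.predict(cluster_data.X) != cluster_data.y) == 0.0

    def test_centroids_classified_as_their_class(self, cluster_data):
        model = plsda_fit(cluster_data.X, cluster_data.y, 1)
        X, y = cluster_data.X, cluster_data.y
        cents = np.vstack([X[y == 0].mean(axis=0), X[y == 1].mean(axis=0)])
        np.testing.assert_array_equal(model.predict(cents), [0, 1])

    def test_feature_count_mismatch(self, cluster_data):
        model = plsda_fit(cluster_data.X, cluster_data.y, 1)
        with pytest.raises(InvalidInputError):
            model.predict(cluster_data.X[:, :5])

    def test_pca_front_end_predicts_when_fit_with_labels(self, cluster_data):
        model = PCA(n_components=2).fit(cluster_data.X, cluster_data.y)
        acc = np.mean(model.predict(cluster_data.X) == cluster_data.y)
        assert acc > 0.95


def test_sign_flip_leaves_predictions_unchanged(cluster_data):
    """Flipping a weight column's sign must not alter centroid predictions."""
    model = plsda_fit(cluster_data.X, cluster_data.y, 2)
    base = model.predict(cluster_data.X)
    model.rotations_ = model.rotations_ * np.array([-1.0, 1.0])
    model.weights_ = model.weights_ * np.array([-1.0, 1.0])
    model.centroids_ = model.centroids_ * np.array([-1.0, 1.0])
    np.testing.assert_array_equal(model.predict(cluster_data.X), base)


def test_sklearn_cross_check(rng):
    """Directions agree with independent implementations on the same data."""
    from sklearn.cross_decomposition import PLSRegression
    from sklearn.decomposition import PCA as SkPCA

    X = rng.normal(size=(50, 8))
    y = rng.integers(0, 2, 50)
    y[:2] = [0, 1]
    ours = pca_fit(X, 3)
    sk = SkPCA(n_components=3).fit(X)
    for h in range(3):
        assert abs(abs(ours.weights_[:, h] @ sk.components_[h]) - 1) < 1e-8
    np.testing.assert_allclose(
        ours.component_importance_, sk.explained_variance_, atol=1e-10
    )
    pls = plsda_fit(X, y, 2)
    skpls = PLSRegression(n_components=2, scale=False).fit(X, y.astype(float))
    for h in range(2):
        assert abs(abs(pls.weights_[:, h] @ skpls.x_weights_[:, h]) - 1) < 1e-8
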