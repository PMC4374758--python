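"""Likelihood, gradient, Gaussian-row completion, rotation, fitting."""

import math

import numpy as np
import pytest

from mixedica.core import (
    ModelCategory,
    ObservationMatrix,
    center_rows,
    complete_gaussian_rows,
    fit,
    gradient,
    loglik,
    negloglik,
    pca_rotate,
)
from mixedica.initialization import random_orthonormal
from mixedica.simulate import SyntheticSpec, amari_style_error, generate
from mixedica.sources import SourceKind

LOG_2PI = math.log(2 * math.pi)


class TestCenterRows:
    def test_simple_row(self):
        data = center_rows(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(data.values, [[-1.0, 0.0, 1.0]])
        np.testing.assert_allclose(data.row_means, [2.0])

    def test_idempotent_on_centered_input(self, rng):
        X = rng.standard_normal((3, 30))
        X -= X.mean(axis=1, keepdims=True)
        data = center_rows(X)
        np.testing.assert_allclose(data.values, X, atol=1e-12)
        np.testing.assert_allclose(data.row_means, 0.0, atol=1e-12)

    def test_rows_sum_to_zero(self, rng):
        data = center_rows(rng.standard_normal((3, 50)) * 100 + 5)
        np.testing.assert_allclose(data.values.sum(axis=1), 0.0, atol=1e-9 * 50 * 100)

    def test_constant_row_rejected(self):
        with pytest.raises(ValueError, match="constant row"):
            center_rows(np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]))

    def test_more_variables_than_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="more variables"):
            center_rows(rng.standard_normal((5, 3)))


class TestLoglik:
    def test_all_gaussian_identity_orthonormal_rows(self):
        """Orthogonal rows with squared norm n at W=I give the pure
        Gaussian constant −(n·m/2)(log 2π + 1)."""
        n, m = 8, 2
        Q, _ = np.linalg.qr(np.random.default_rng(0).standard_normal((n, m)))
        X = math.sqrt(n) * Q.T  # rows orthogonal, squared norm n, zero-sum? no
        X -= X.mean(axis=1, keepdims=True)
        # re-orthogonalize after centering
        U, d, Vt = np.linalg.svd(X, full_matrices=False)
        X = math.sqrt(n) * (U @ Vt)
        data = ObservationMatrix(X, np.zeros(m))
        cat = ModelCategory(0, 0, m)
        ll = loglik(np.eye(m), data, cat)
        assert -ll == pytest.approx((n * m / 2) * (LOG_2PI + 1), rel=1e-12)

    def test_single_super_source_at_zero(self):
        """cosh(0) = 1 leaves only the log 2 normalization."""
        data = ObservationMatrix(np.array([[0.0, 0.0]]), np.zeros(1))
        cat = ModelCategory(0, 1, 0)
        assert negloglik(np.eye(1), data, cat, form="direct") == pytest.approx(
            2 * math.log(2)
        )

    def test_constrained_form_equals_direct_sum(self, rng):
        """The Gaussian-constant form agrees with the full per-entry sum
        whenever the Gaussian rows satisfy their constraints."""
        data = center_rows(rng.standard_normal((4, 60)))
        cat = ModelCategory(1, 1, 2)
        W_free = rng.standard_normal((2, 4))
        W = complete_gaussian_rows(W_free, data, 2)
        assert loglik(W, data, cat) == pytest.approx(
            loglik(W, data, cat, form="direct"), abs=1e-8
        )

    def test_constraint_violation_detected(self, small_data):
        cat = ModelCategory(1, 1, 1)
        W = np.eye(3) + 0.3
        with pytest.raises(ValueError, match="constraint"):
            loglik(W, small_data, cat)

    def test_singular_w_rejected(self, small_data, mixed_category):
        with pytest.raises(np.linalg.LinAlgError):
            loglik(np.zeros((3, 3)), small_data, mixed_category, form="direct")


class TestGradient:
    @pytest.mark.parametrize("cat", [ModelCategory(1, 1, 1), ModelCategory(2, 1, 0),
                                     ModelCategory(0, 1, 2)])
    def test_matches_finite_differences(self, rng, cat):
        data = center_rows(rng.standard_normal((3, 40)))
        W = np.eye(3) + 0.2 * rng.standard_normal((3, 3))
        g = gradient(W, data, cat)
        h = 1e-6
        for i in range(3):
            for j in range(3):
                Wp, Wm = W.copy(), W.copy()
                Wp[i, j] += h
                Wm[i, j] -= h
                fd = (
                    loglik(Wp, data, cat, form="direct")
                    - loglik(Wm, data, cat, form="direct")
                ) / (2 * h)
                assert g[i, j] == pytest.approx(fd, abs=1e-5 * max(1, abs(fd)))

    def test_gaussian_rows_zero_after_completion(self, rng):
        """Under the orthogonal-completion parameterization the Gaussian
        rows of the gradient vanish identically."""
        data = center_rows(rng.standard_normal((4, 50)))
        cat = ModelCategory(1, 1, 2)
        W = complete_gaussian_rows(rng.standard_normal((2, 4)), data, 2)
        dW = gradient(W, data, cat)
        np.testing.assert_allclose(dW[2:], 0.0, atol=1e-8 * data.n)

    def test_gradient_small_at_optimum(self, rng):
        X, _ = generate(
            SyntheticSpec([SourceKind.SUPER, SourceKind.SUPER], "rotation:30",
                          n=500, seed=1)
        )
        data = center_rows(X)
        cat = ModelCategory(0, 2, 0)
        model = fit(data, cat)
        dW = gradient(model.W, data, cat)
        assert np.abs(dW).max() < 1e-4 * data.n


class TestCompletion:
    def test_no_gaussian_rows_returns_input(self, small_data, rng):
        W_free = rng.standard_normal((3, 3))
        np.testing.assert_array_equal(
            complete_gaussian_rows(W_free, small_data, 0), W_free
        )

    def test_all_gaussian_gives_orthogonal_basis(self, small_data):
        W = complete_gaussian_rows(np.empty((0, 3)), small_data, 3)
        S = W @ small_data.values
        np.testing.assert_allclose(
            S @ S.T, small_data.n * np.eye(3), atol=1e-6 * small_data.n
        )

    def test_gaussian_block_constraints(self, rng):
        data = center_rows(rng.standard_normal((5, 80)))
        W_free = rng.standard_normal((2, 5))
        W = complete_gaussian_rows(W_free, data, 3)
        S = W @ data.values
        np.testing.assert_allclose(
            S[2:] @ S[2:].T, data.n * np.eye(3), atol=1e-6 * data.n
        )
        np.testing.assert_allclose(S[:2] @ S[2:].T, 0.0, atol=1e-6 * data.n)
        np.testing.assert_allclose(W @ data.values, S, atol=1e-10)

    def test_rank_deficient_free_rows_rejected(self, small_data):
        W_free = np.array([[1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        with pytest.raises(np.linalg.LinAlgError):
            complete_gaussian_rows(W_free, small_data, 1)


class TestPcaRotate:
    def _fitted(self, rng, n_gauss=3):
        data = center_rows(rng.standard_normal((4, 100)) * [[3], [2], [1], [0.5]])
        cat = ModelCategory(0, 4 - n_gauss, n_gauss)
        return fit(data, cat), data

    def test_loglik_invariant(self, rng):
        model, data = self._fitted(rng)
        assert loglik(model.W, data, model.category, form="direct") == pytest.approx(
            model.loglik, abs=1e-9 * abs(model.loglik)
        )

    def test_gaussian_components_ordered_by_variance(self, rng):
        model, data = self._fitted(rng)
        k = model.category.n_free
        contrib = [
            np.sum(np.outer(model.A[:, i], model.S[i]) ** 2)
            for i in range(k, model.m)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(contrib, contrib[1:]))

    def test_rotated_rows_eigenvectors_of_gaussian_gram(self, rng):
        """Within the Gaussian span, rotated source rows diagonalize the
        contribution A_g·S_g of the subspace to the data."""
        model, data = self._fitted(rng)
        k = model.category.n_free
        Xg = model.A[:, k:] @ model.S[k:]
        # each rotated row must be an eigenvector direction of Xg Xg^T via A
        G = model.A[:, k:].T @ model.A[:, k:]
        off = G - np.diag(np.diag(G))
        np.testing.assert_allclose(off, 0.0, atol=1e-8 * np.abs(G).max())

    def test_single_gaussian_component_unchanged(self, rng):
        data = center_rows(rng.standard_normal((3, 60)))
        cat = ModelCategory(1, 1, 1)
        model = fit(data, cat)
        again = pca_rotate(model)
        np.testing.assert_allclose(np.abs(again.W), np.abs(model.W), atol=1e-10)


class TestFit:
    def test_all_gaussian_equals_closed_form_ml(self, rng):
        """The PCA fit reaches the multivariate-normal ML likelihood."""
        X = rng.standard_normal((3, 120)) * [[2], [1], [0.5]]
        data = center_rows(X)
        model = fit(data, ModelCategory(0, 0, 3))
        n, m = data.n, data.m
        Sig = data.values @ data.values.T / n
        ref = -(n / 2) * (m * LOG_2PI + np.linalg.slogdet(Sig)[1] + m)
        assert model.loglik == pytest.approx(ref, abs=1e-6 * abs(ref))

    def test_thirty_degree_rotation_recovery(self):
        """Two heavy-tailed sources mixed by a 30° rotation are recovered
        almost perfectly at n = 2000."""
        X, truth = generate(
            SyntheticSpec([SourceKind.SUPER] * 2, "rotation:30", n=2000, seed=3)
        )
        data = center_rows(X)
        model = fit(data, ModelCategory(0, 2, 0))
        S_true = truth["S_true"]
        C = np.abs(np.corrcoef(S_true, model.S)[:2, 2:])
        # best match per true source exceeds 0.99
        assert C.max(axis=1).min() > 0.99
        assert amari_style_error(model.W, truth["A_true"]) < 0.05

    def test_already_unmixed_identity_start(self):
        X, truth = generate(
            SyntheticSpec([SourceKind.SUB, SourceKind.SUPER], "identity",
                          n=2000, seed=4)
        )
        data = center_rows(X)
        model = fit(data, ModelCategory(1, 1, 0), W_init=np.eye(2))
        C = np.abs(np.corrcoef(truth["S_true"], model.S)[:2, 2:])
        assert C.max(axis=1).min() > 0.99

    def test_never_below_initialization(self, rng):
        data = center_rows(rng.standard_normal((3, 50)))
        cat = ModelCategory(1, 1, 1)
        W0 = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
        from mixedica.core import complete_gaussian_rows as cgr

        W0c = cgr(W0[:2], data, 1)
        ll0 = loglik(W0c, data, cat)
        model = fit(data, cat, W_init=W0)
        assert model.loglik >= ll0 - 1e-9

    def test_invariance_under_orthonormal_pre_rotation(self, rng):
        """Pre-rotating the data by an orthonormal Q leaves the maximized
        likelihood unchanged (sources are identical; W absorbs Qᵀ)."""
        X, _ = generate(
            SyntheticSpec([SourceKind.SUPER] * 2 + [SourceKind.GAUSS],
                          "random-cond:3", n=400, seed=5)
        )
        data = center_rows(X)
        cat = ModelCategory(0, 2, 1)
        m1 = fit(data, cat)
        Q = random_orthonormal(3, rng)
        m2 = fit(center_rows(Q @ X), cat, W_init=m1.W @ Q.T)
        assert m2.loglik == pytest.approx(m1.loglik, abs=1e-5 * abs(m1.loglik))

    def test_model_invariants(self, rng):
        data = center_rows(rng.standard_normal((4, 80)))
        model = fit(data, ModelCategory(1, 1, 2))
        np.testing.assert_allclose(model.W @ model.A, np.eye(4), atol=1e-8)
        np.testing.assert_allclose(model.S, model.W @ data.values, atol=1e-8)
        G = model.S[2:]
        np.testing.assert_allclose(G @ G.T, data.n * np.eye(2), atol=1e-6 * data.n)
        np.testing.assert_allclose(model.S[:2] @ G.T, 0, atol=1e-6 * data.n)
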