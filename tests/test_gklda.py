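"""Scatter matrices, kernel matrix, generalized eigenproblem, projection."""

import numpy as np
import pytest

from securedx.errors import ValidationError
from securedx.gklda import (
    GaussianKernelLDA,
    fisher_criterion,
    gaussian_kernel_matrix,
    class_statistics,
    load_basis,
    project,
    save_basis,
    scatter_matrices,
    solve_discriminant,
)

TOY_X = np.array([0.0, 2.0, 4.0, 6.0])[:, None]
TOY_Y = np.array([0, 0, 1, 1])


def brute_force_lda(X, y, reg):
    """Oracle: explicit W^-1 B eigendecomposition (dense, unsymmetric)."""
    pair = scatter_matrices(X, y)
    W = pair.within + reg * np.eye(pair.within.shape[0])
    vals = np.linalg.eigvals(np.linalg.inv(W) @ pair.between)
    return np.sort(np.real(vals))[::-1]


class TestClassStatistics:
    def test_hand_values(self):
        means, grand, sizes = class_statistics(TOY_X, TOY_Y)
        assert means[0] == pytest.approx(1.0)
        assert means[1] == pytest.approx(5.0)
        assert grand == pytest.approx(3.0)
        assert sizes == {0: 2, 1: 2}

    def test_single_class_grand_equals_class_mean(self):
        means, grand, _ = class_statistics(np.array([[1.0], [3.0]]), [7, 7])
        assert means[7] == pytest.approx(grand)

    def test_permutation_invariance(self, gaussian_5class):
        X, y = gaussian_5class
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(X))
        m1, g1, s1 = class_statistics(X, y)
        m2, g2, s2 = class_statistics(X[perm], y[perm])
        np.testing.assert_allclose(g1, g2)
        for c in m1:
            np.testing.assert_allclose(m1[c], m2[c])
        assert s1 == s2


class TestScatterMatrices:
    def test_hand_worked_example(self):
        pair = scatter_matrices(TOY_X, TOY_Y)
        assert pair.between[0, 0] == pytest.approx(16.0, abs=1e-12)
        assert pair.within[0, 0] == pytest.approx(4.0, abs=1e-12)

    def test_brute_force_double_loop_oracle(self, gaussian_5class):
        X, y = gaussian_5class
        pair = scatter_matrices(X, y)
        mu = X.mean(axis=0)
        B = np.zeros_like(pair.between)
        W = np.zeros_like(pair.within)
        for c in np.unique(y):
            Xc = X[y == c]
            d = (Xc.mean(axis=0) - mu)[:, None]
            B += len(Xc) * d @ d.T
            for row in Xc:
                e = (row - Xc.mean(axis=0))[:, None]
                W += e @ e.T
        np.testing.assert_allclose(pair.between, B, atol=1e-8)
        np.testing.assert_allclose(pair.within, W, atol=1e-8)

    def test_symmetric_psd(self, gaussian_5class):
        X, y = gaussian_5class
        pair = scatter_matrices(X, y)
        for M in (pair.between, pair.within):
            np.testing.assert_allclose(M, M.T, atol=1e-10)
            assert np.linalg.eigvalsh(M).min() >= -1e-10

    def test_trace_decomposition(self, gaussian_5class):
        # tr(B) + tr(W) = total scatter about the grand mean
        X, y = gaussian_5class
        pair = scatter_matrices(X, y)
        total = ((X - X.mean(axis=0)) ** 2).sum()
        assert np.trace(pair.between) + np.trace(pair.within) == pytest.approx(
            total, abs=1e-8
        )

    def test_degenerate_cases(self):
        # identical class means -> zero between-scatter
        X = np.array([[0.0], [2.0], [0.0], [2.0]])
        pair = scatter_matrices(X, [0, 0, 1, 1])
        np.testing.assert_allclose(pair.between, 0.0, atol=1e-12)
        # single-point classes -> zero within-scatter
        pair = scatter_matrices(np.array([[0.0], [5.0]]), [0, 1])
        np.testing.assert_allclose(pair.within, 0.0, atol=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            scatter_matrices(np.array([[1.0], [2.0]]), [0, 0])


class TestKernelMatrix:
    def test_unit_diagonal_symmetric_bounded(self, gaussian_5class):
        X, _ = gaussian_5class
        km = gaussian_kernel_matrix(X[:40], gamma=0.3)
        np.testing.assert_allclose(np.diag(km.values), 1.0)
        np.testing.assert_allclose(km.values, km.values.T)
        assert km.values.min() > 0.0 and km.values.max() <= 1.0

    def test_small_gamma_limit_all_ones(self, gaussian_5class):
        X, _ = gaussian_5class
        km = gaussian_kernel_matrix(X[:20], gamma=1e-12)
        np.testing.assert_allclose(km.values, 1.0, atol=1e-6)

    def test_median_heuristic_positive(self, gaussian_5class):
        X, _ = gaussian_5class
        km = gaussian_kernel_matrix(X[:30], "median-heuristic")
        assert km.gamma > 0

    def test_nonpositive_gamma_rejected(self):
        with pytest.raises(ValidationError):
            gaussian_kernel_matrix(np.eye(3), gamma=0.0)


class TestSolveDiscriminant:
    def test_toy_eigenvalue_is_four(self):
        basis = solve_discriminant(
            TOY_X, TOY_Y, mode="linear", regularization=0.0
        )
        assert basis.eigenvalues[0] == pytest.approx(4.0, abs=1e-12)

    def test_zero_between_gives_zero_eigenvalues(self):
        X = np.array([[0.0], [2.0], [0.0], [2.0]])
        basis = solve_discriminant(X, [0, 0, 1, 1], mode="linear")
        np.testing.assert_allclose(basis.eigenvalues, 0.0, atol=1e-10)

    def test_generalized_eigen_residual(self, gaussian_5class):
        X, y = gaussian_5class
        basis = solve_discriminant(X, y, mode="linear")
        pair = scatter_matrices(X, y)
        W_reg = pair.within + basis.regularization * np.eye(X.shape[1])
        for j in range(basis.n_components):
            r = basis.vectors[:, j]
            lam = basis.eigenvalues[j]
            lhs = pair.between @ r
            assert np.linalg.norm(lhs - lam * W_reg @ r) <= 1e-8 * max(
                np.linalg.norm(lhs), 1e-30
            )

    def test_eigenvalues_nonincreasing_and_c_minus_1(self, gaussian_5class):
        X, y = gaussian_5class
        basis = solve_discriminant(X, y, mode="linear")
        assert basis.n_components == 4
        assert np.all(np.diff(basis.eigenvalues) <= 1e-10)

    def test_linear_mode_matches_brute_force_oracle(self, gaussian_5class):
        X, y = gaussian_5class
        reg = 1e-3
        basis = solve_discriminant(X, y, mode="linear", regularization=reg)
        oracle = brute_force_lda(X, y, reg)[: basis.n_components]
        np.testing.assert_allclose(
            basis.eigenvalues, oracle, rtol=1e-6, atol=1e-12
        )

    def test_solved_basis_beats_random_bases(self, gaussian_5class):
        X, y = gaussian_5class
        basis = solve_discriminant(X, y, mode="linear")
        crit = fisher_criterion(X, y, basis.vectors)
        rng = np.random.default_rng(2024)
        k = basis.n_components
        for _ in range(100):
            Q, _ = np.linalg.qr(rng.normal(size=(X.shape[1], k)))
            assert crit > fisher_criterion(X, y, Q)

    def test_deterministic_sign_and_refit(self, gaussian_5class):
        X, y = gaussian_5class
        b1 = solve_discriminant(X, y, mode="linear")
        b2 = solve_discriminant(X, y, mode="linear")
        np.testing.assert_array_equal(b1.vectors, b2.vectors)
        for j in range(b1.n_components):
            i = np.argmax(np.abs(b1.vectors[:, j]))
            assert b1.vectors[i, j] > 0


class TestProjection:
    def test_two_class_gives_one_column(self, small_table):
        from securedx.preprocess import preprocess_table

        m = preprocess_table(small_table)
        basis = solve_discriminant(m.values, m.labels, mode="linear")
        out = project(m.values, basis)
        assert out.shape == (m.n_rows, 1)

    def test_identity_basis_preserves_input(self, gaussian_5class):
        from securedx.gklda import ProjectionBasis

        X, _ = gaussian_5class
        basis = ProjectionBasis(
            vectors=np.eye(X.shape[1]),
            eigenvalues=np.ones(X.shape[1]),
            n_components=X.shape[1],
            regularization=0.0,
            mode="linear",
        )
        np.testing.assert_array_equal(project(X, basis), X)

    def test_dimension_mismatch_rejected(self, gaussian_5class):
        X, y = gaussian_5class
        basis = solve_discriminant(X, y, mode="linear")
        with pytest.raises(ValidationError):
            project(X[:, :3], basis)

    def test_kernel_projection_consistent_with_training_scores(
        self, gaussian_5class
    ):
        X, y = gaussian_5class
        results = GaussianKernelLDA(mode="kernel", gamma=0.5).fit(X, y)
        np.testing.assert_allclose(
            results.transform(X), results.training_scores, atol=1e-12
        )

    def test_kernel_mode_separates_classes(self, gaussian_5class):
        # projected class means should be distinct along the top component
        X, y = gaussian_5class
        results = GaussianKernelLDA(mode="kernel").fit(X, y)
        scores = results.training_scores[:, 0]
        means = [scores[y == c].mean() for c in np.unique(y)]
        assert len({round(m, 6) for m in means}) == len(means)


class TestModelObjects:
    def test_summary_mentions_mode_and_eigenvalues(self, gaussian_5class):
        X, y = gaussian_5class
        results = GaussianKernelLDA(mode="linear").fit(X, y)
        text = results.summary()
        assert "linear" in text
        assert "eigenvalues" in text

    def test_basis_persistence_round_trip(self, tmp_path, gaussian_5class):
        X, y = gaussian_5class
        for mode in ("linear", "kernel"):
            basis = solve_discriminant(X, y, mode=mode, gamma=0.4)
            path = tmp_path / f"basis_{mode}.txt"
            save_basis(basis, path)
            loaded = load_basis(path)
            np.testing.assert_array_equal(loaded.vectors, basis.vectors)
            np.testing.assert_array_equal(
                loaded.eigenvalues, basis.eigenvalues
            )
            np.testing.assert_allclose(
                project(X[:10], loaded), project(X[:10], basis), atol=1e-12
            )
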