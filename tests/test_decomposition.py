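import numpy as np
import pytest
import scipy.linalg

from crossdecomp import (
    METHODS,
    NumericalError,
    ValidationError,
    fit_cca,
    fit_method,
    fit_plsc,
    fit_plsr,
    predict_plsr,
    structure_coefficients,
)

from conftest import make_block, random_blocks


def _centered(block):
    return block.values - block.values.mean(axis=0)


def cca_oracle(X, Y):
    """Canonical correlations via the generalized eigenproblem (dense solve)."""
    Xc, Yc = _centered(X), _centered(Y)
    n = len(Xc)
    Sx = Xc.T @ Xc / (n - 1)
    Sy = Yc.T @ Yc / (n - 1)
    Cxy = Xc.T @ Yc / (n - 1)
    M = np.linalg.inv(Sx) @ Cxy @ np.linalg.inv(Sy) @ Cxy.T
    ev = np.sort(np.real(scipy.linalg.eig(M)[0]))[::-1]
    return np.sqrt(np.clip(ev, 0, None))


def whiten(block):
    """Transform so the sample covariance is exactly the identity."""
    Xc = _centered(block)
    S = Xc.T @ Xc / (len(Xc) - 1)
    w, Q = np.linalg.eigh(S)
    return block.with_values(Xc @ (Q * (1 / np.sqrt(w))) @ Q.T)


class TestCCA:
    def test_perfect_linear_relationship(self, rng):
        X = make_block(rng.standard_normal((50, 3)), "x")
        M = rng.standard_normal((3, 3)) + 2 * np.eye(3)
        Y = make_block(X.values @ M, "y")
        fit = fit_cca(X, Y, k=3)
        np.testing.assert_allclose(fit.assoc, 1.0, atol=1e-8)

    def test_affine_invariance(self, rng):
        X, Y = random_blocks(rng, 40, 4, 3)
        A = rng.standard_normal((4, 4)) + 2 * np.eye(4)
        B = rng.standard_normal((3, 3)) + 2 * np.eye(3)
        base = fit_cca(X, Y, k=3)
        mixed = fit_cca(
            make_block(X.values @ A, "x"), make_block(Y.values @ B, "y"), k=3
        )
        np.testing.assert_allclose(mixed.assoc, base.assoc, atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_generalized_eigenproblem_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X, Y = random_blocks(rng, 30, 3, 2)
        fit = fit_cca(X, Y, k=2)
        np.testing.assert_allclose(fit.assoc, cca_oracle(X, Y)[:2], atol=1e-8)

    def test_canonical_variates_orthonormal_correlation(self, rng):
        X, Y = random_blocks(rng, 60, 5, 4)
        fit = fit_cca(X, Y, k=4)
        for scores in (fit.T, fit.S):
            corr = np.corrcoef(scores.T)
            np.testing.assert_allclose(corr, np.eye(4), atol=1e-6)

    def test_assoc_descending_in_unit_interval(self, rng):
        X, Y = random_blocks(rng, 50, 6, 4)
        fit = fit_cca(X, Y, k=4)
        assert np.all(fit.assoc >= 0) and np.all(fit.assoc <= 1)
        assert np.all(np.diff(fit.assoc) <= 1e-12)

    def test_singular_covariance_recommends_ridge(self, rng):
        vals = rng.standard_normal((20, 3))
        X = make_block(np.column_stack([vals, vals[:, 0]]), "x")
        Y = make_block(rng.standard_normal((20, 2)), "y")
        with pytest.raises(NumericalError, match="ridge"):
            fit_cca(X, Y, k=2)
        fit = fit_cca(X, Y, k=2, ridge="auto")  # regularized path succeeds
        assert np.all(np.isfinite(fit.assoc))

    def test_k_out_of_range(self, rng):
        X, Y = random_blocks(rng, 30, 3, 2)
        with pytest.raises(ValidationError, match="k="):
            fit_cca(X, Y, k=3)


class TestPLSC:
    def test_scalar_blocks(self, rng):
        X, Y = random_blocks(rng, 25, 1, 1)
        fit = fit_plsc(X, Y, k=1)
        cov = np.cov(X.values[:, 0], Y.values[:, 0], ddof=1)[0, 1]
        np.testing.assert_allclose(fit.assoc[0], abs(cov), atol=1e-12)
        assert abs(abs(fit.U[0, 0]) - 1.0) < 1e-12
        assert abs(abs(fit.V[0, 0]) - 1.0) < 1e-12

    def test_brute_force_covariance_maximization(self, rng):
        X, Y = random_blocks(rng, 20, 3, 2)
        fit = fit_plsc(X, Y, k=2)
        Xc, Yc = _centered(X), _centered(Y)
        C = Xc.T @ Yc / 19
        best = 0.0
        for _ in range(10_000):
            u = rng.standard_normal(3)
            v = rng.standard_normal(2)
            val = u @ C @ v / (np.linalg.norm(u) * np.linalg.norm(v))
            best = max(best, abs(val))
        assert best <= fit.assoc[0] + 1e-9  # sampling never beats the SVD
        # power refinement from the SVD pair confirms equality at the optimum
        u, v = fit.U[:, 0], fit.V[:, 0]
        for _ in range(200):
            u = C @ v / np.linalg.norm(C @ v)
            v = C.T @ u / np.linalg.norm(C.T @ u)
        np.testing.assert_allclose(abs(u @ C @ v), fit.assoc[0], atol=1e-8)

    def test_whitened_blocks_reduce_to_cca(self, rng):
        X, Y = random_blocks(rng, 40, 4, 3)
        Xw, Yw = whiten(X), whiten(Y)
        plsc = fit_plsc(Xw, Yw, k=3)
        cca = fit_cca(Xw, Yw, k=3)
        np.testing.assert_allclose(plsc.assoc, cca.assoc, atol=1e-6)
        for c in range(3):
            sign = np.sign(plsc.U[:, c] @ cca.U[:, c])
            np.testing.assert_allclose(plsc.U[:, c], sign * cca.U[:, c], atol=1e-6)
            np.testing.assert_allclose(plsc.V[:, c], sign * cca.V[:, c], atol=1e-6)

    def test_assoc_squared_sums_to_frobenius(self, rng):
        X, Y = random_blocks(rng, 30, 5, 3)
        fit = fit_plsc(X, Y, k=3)
        Xc, Yc = _centered(X), _centered(Y)
        C = Xc.T @ Yc / 29
        np.testing.assert_allclose(
            np.sum(fit.assoc**2), np.linalg.norm(C) ** 2, atol=1e-8
        )

    def test_k_beyond_rank(self, rng):
        z = rng.standard_normal(20)
        X = make_block(np.column_stack([z, 2 * z, -z]), "x")  # rank-1 cross-cov
        Y = make_block(rng.standard_normal((20, 3)), "y")
        Yr = make_block(np.outer(Y.values @ np.ones(3), np.ones(3)), "y")
        with pytest.raises(ValidationError, match="rank"):
            fit_plsc(X, Yr, k=2)


class TestPLSR:
    def test_first_component_matches_plsc_weight(self, rng):
        X, Y = random_blocks(rng, 30, 4, 3)
        plsr = fit_plsr(X, Y, k=1)
        plsc = fit_plsc(X, Y, k=1)
        sign = np.sign(plsr.U[:, 0] @ plsc.U[:, 0])
        np.testing.assert_allclose(plsr.U[:, 0], sign * plsc.U[:, 0], atol=1e-8)

    def test_full_rank_single_response_is_ols(self, rng):
        X = make_block(rng.standard_normal((40, 4)), "x")
        Y = make_block(rng.standard_normal((40, 1)), "y")
        fit = fit_plsr(X, Y, k=4)
        Xc, Yc = _centered(X), _centered(Y)
        ols = np.linalg.lstsq(Xc, Yc, rcond=None)[0]
        np.testing.assert_allclose(fit.coef, ols, atol=1e-6)

    @pytest.mark.parametrize("seed", [0, 7])
    def test_reference_implementation_oracle(self, seed):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(seed)
        X, Y = random_blocks(rng, 25, 4, 3)
        fit = fit_plsr(X, Y, k=3)
        ref = sklearn.PLSRegression(
            n_components=3, scale=False, tol=1e-24, max_iter=5000
        ).fit(_centered(X), _centered(Y))
        for c in range(3):
            sign = np.sign(fit.T[:, c] @ ref.x_scores_[:, c])
            np.testing.assert_allclose(
                fit.T[:, c], sign * ref.x_scores_[:, c], atol=1e-6
            )
        np.testing.assert_allclose(fit.coef, ref.coef_.T, atol=1e-6)

    def test_deflation_exhausts_x(self, rng):
        X, Y = random_blocks(rng, 20, 4, 3)
        fit = fit_plsr(X, Y, k=4)  # k = rank(X)
        assert fit.diagnostics["x_residual_fro"] < 1e-6

    def test_scores_follow_rotation_identity(self, rng):
        X, Y = random_blocks(rng, 30, 5, 2)
        fit = fit_plsr(X, Y, k=2)
        np.testing.assert_allclose(fit.T, _centered(X) @ fit.U, atol=1e-8)
        np.testing.assert_allclose(fit.S, _centered(Y) @ fit.V, atol=1e-8)

    def test_predict_approximates_y(self, rng):
        X = make_block(rng.standard_normal((60, 3)), "x")
        B = rng.standard_normal((3, 2))
        Y = make_block(X.values @ B + 0.01 * rng.standard_normal((60, 2)), "y")
        fit = fit_plsr(X, Y, k=3)
        pred = predict_plsr(fit, X.values)
        assert np.abs(pred - Y.values).max() < 0.1

    def test_predict_requires_plsr(self, rng):
        X, Y = random_blocks(rng, 20, 3, 2)
        with pytest.raises(ValidationError, match="no predictive"):
            predict_plsr(fit_plsc(X, Y, k=1), X.values)

    def test_k_beyond_rank(self, rng):
        X, Y = random_blocks(rng, 10, 3, 2)
        with pytest.raises(ValidationError, match="rank"):
            fit_plsr(X, Y, k=4)


class TestSharedContracts:
    def test_scores_equal_projections(self, rng):
        X, Y = random_blocks(rng, 40, 5, 3)
        Xs = make_block(
            (X.values - X.values.mean(0)) / X.values.std(0, ddof=1), "x"
        )
        Ys = make_block(
            (Y.values - Y.values.mean(0)) / Y.values.std(0, ddof=1), "y"
        )
        for method in METHODS:
            fit = fit_method(method, Xs, Ys, k=2)
            np.testing.assert_allclose(fit.T, Xs.values @ fit.U, atol=1e-8)
            np.testing.assert_allclose(fit.S, Ys.values @ fit.V, atol=1e-8)

    def test_sign_convention_largest_v_entry_positive(self, rng):
        X, Y = random_blocks(rng, 50, 6, 4)
        for method in METHODS:
            fit = fit_method(method, X, Y, k=3)
            for c in range(fit.k):
                j = np.argmax(np.abs(fit.V[:, c]))
                assert fit.V[j, c] > 0

    def test_rescaling_changes_pls_but_not_cca(self, rng):
        X, Y = random_blocks(rng, 40, 4, 3)
        D = np.diag([5.0, 1.0, 0.2, 1.0])
        Xr = make_block(X.values @ D, "x")
        cca_a, cca_b = fit_cca(X, Y, k=2), fit_cca(Xr, Y, k=2)
        np.testing.assert_allclose(cca_a.assoc, cca_b.assoc, atol=1e-8)
        for fitter in (fit_plsc, fit_plsr):
            a, b = fitter(X, Y, k=2), fitter(Xr, Y, k=2)
            assert np.abs(a.assoc - b.assoc).max() > 1e-4

    def test_determinism_bit_for_bit(self, rng):
        X, Y = random_blocks(rng, 30, 4, 3)
        for method in METHODS:
            f1 = fit_method(method, X, Y, k=2)
            f2 = fit_method(method, X, Y, k=2)
            assert np.array_equal(f1.U, f2.U)
            assert np.array_equal(f1.V, f2.V)
            assert np.array_equal(f1.assoc, f2.assoc)

    def test_unknown_method(self, rng):
        X, Y = random_blocks(rng, 20, 3, 2)
        with pytest.raises(ValidationError, match="unknown method"):
            fit_method("OPLS", X, Y)


class TestStructureCoefficients:
    def test_single_variable_self_correlation(self, rng):
        X, Y = random_blocks(rng, 25, 1, 1)
        fit = fit_plsc(X, Y, k=1)
        xl, yl = structure_coefficients(fit, X, Y)
        np.testing.assert_allclose(abs(xl[0, 0]), 1.0, atol=1e-10)

    def test_bounded_by_one(self, rng):
        X, Y = random_blocks(rng, 30, 5, 4)
        for method in METHODS:
            fit = fit_method(method, X, Y, k=3)
            assert np.all(np.abs(fit.x_loadings) <= 1.0)
            assert np.all(np.abs(fit.y_loadings) <= 1.0)

    def test_direct_loop_oracle(self, rng):
        X, Y = random_blocks(rng, 20, 3, 2)
        fit = fit_cca(X, Y, k=2)
        xl, yl = structure_coefficients(fit, X, Y)
        for j in range(3):
            for c in range(2):
                expected = np.corrcoef(X.values[:, j], fit.T[:, c])[0, 1]
                np.testing.assert_allclose(xl[j, c], expected, atol=1e-10)
        for j in range(2):
            for c in range(2):
                expected = np.corrcoef(Y.values[:, j], fit.S[:, c])[0, 1]
                np.testing.assert_allclose(yl[j, c], expected, atol=1e-10)

    def test_wrong_blocks_rejected(self, rng):
        X, Y = random_blocks(rng, 20, 3, 2)
        fit = fit_cca(X, Y, k=2)
        Xother = make_block(rng.standard_normal((20, 3)), "z")
        with pytest.raises(ValidationError, match="variable sets"):
            structure_coefficients(fit, Xother, Y)


class TestSyntheticLeadingComponent:
    def test_general_factor_dominates_leading_loadings(self, default_fits):
        for method, fit in default_fits.items():
            j = np.argmax(np.abs(fit.y_loadings[:, 0]))
            assert fit.y_names[j] == "general", method
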