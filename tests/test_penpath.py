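import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from pglmm.kinship import eigendecompose
from pglmm.nullmodel import BinomialFamily, fit_null
from pglmm.penpath import (PenaltySpec, adaptive_weights, build_rotated,
                           cd_fit, default_penalty_factors, fit_path,
                           kkt_violation, lambda_grid, profile_b,
                           soft_threshold)
from pglmm._cd import cd_sweeps

from _oracles import fista_pql, gaussian_pen_lmm_oracle, pql_objective
from conftest import random_psd


class TestSoftThreshold:
    @pytest.mark.parametrize("z,t,expected", [
        (3.0, 1.0, 2.0),
        (-0.5, 1.0, 0.0),
        (1.7, 0.0, 1.7),
        (-3.0, 1.0, -2.0),
    ])
    def test_examples(self, z, t, expected):
        assert soft_threshold(z, t) == pytest.approx(expected)

    @given(st.floats(-1e6, 1e6), st.floats(0, 1e6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_shrinks_toward_zero(self, z, t):
        s = soft_threshold(z, t)
        assert abs(s) <= abs(z) + 1e-12
        assert abs(s) == pytest.approx(max(abs(z) - t, 0.0), abs=1e-9)


class TestBuildRotated:
    def test_tau_zero_limit(self, rng):
        km = eigendecompose([np.eye(12)], [0.0])
        X = rng.normal(size=(12, 3))
        rs = build_rotated(None, km, X)
        np.testing.assert_allclose(rs.w, 0.25)
        np.testing.assert_allclose(rs.shrink, 0.0)

    def test_large_eigenvalue_limit(self, rng):
        km = eigendecompose([1e9 * np.eye(6)], [1.0])
        rs = build_rotated(None, km, rng.normal(size=(6, 2)))
        assert np.all(rs.shrink > 1 - 1e-6)
        assert np.all(rs.w < 1e-8)

    def test_shrink_weight_identity(self, rng):
        km = eigendecompose([random_psd(rng, 10)], [0.7])
        rs = build_rotated(None, km, rng.normal(size=(10, 4)))
        np.testing.assert_allclose(rs.shrink, 1 - rs.c_bound * rs.w,
                                   atol=1e-12)

    def test_weighted_gram_equals_dense_inverse(self, rng):
        # (X*)' diag(w) X* = X' (4I + K)^-1 X
        n = 20
        V = random_psd(rng, n)
        km = eigendecompose([V], [1.4])
        X = rng.normal(size=(n, 5))
        rs = build_rotated(None, km, X)
        lhs = rs.Xstar.T @ (rs.w[:, None] * rs.Xstar)
        rhs = X.T @ np.linalg.inv(4 * np.eye(n) + 1.4 * V) @ X
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_surrogate_is_lower_bound_on_sigma(self, fitted_glmm):
        # W <= I/4 so W^-1 >= 4I: Sigma dominates the fixed surrogate
        # Sigma_b = 4I + K, i.e. Sigma_b^-1 majorizes Sigma^-1 (valid MM step)
        nf, V = fitted_glmm["null"], fitted_glmm["V"]
        Sigma = np.diag(1 / nf.W) + nf.tau[0] * V
        Sigma_b = 4 * np.eye(len(nf.W)) + nf.tau[0] * V
        assert np.linalg.eigvalsh(Sigma - Sigma_b).min() > -1e-8


class TestProfileB:
    def test_tau_zero_gives_zero(self, rng):
        km = eigendecompose([np.eye(8)], [0.0])
        X = rng.normal(size=(8, 2))
        rs = build_rotated(None, km, X)
        b = profile_b(rs, rng.normal(size=8), np.zeros(2))
        np.testing.assert_allclose(b, 0.0)

    def test_scalar_shrinkage_case(self, rng):
        # V = I, tau = c, beta = 0: b = c/(4+c) * Ytilde
        c = 2.5
        km = eigendecompose([np.eye(9)], [c])
        X = rng.normal(size=(9, 2))
        rs = build_rotated(None, km, X)
        yt = rng.normal(size=9)
        b = profile_b(rs, km.U.T @ yt, np.zeros(2))
        np.testing.assert_allclose(b, c / (4 + c) * yt, atol=1e-10)

    def test_matches_normal_equations(self, rng):
        # b minimizes (1/4)||yt - Xb beta - b||^2 + 0.5 b' K^-1 b
        n = 15
        V = random_psd(rng, n)
        tau = 0.9
        km = eigendecompose([V], [tau])
        X = rng.normal(size=(n, 3))
        rs = build_rotated(None, km, X)
        beta = rng.normal(size=3)
        yt = rng.normal(size=n)
        b = profile_b(rs, km.U.T @ yt, beta)
        K = tau * V
        oracle = np.linalg.solve(np.eye(n) / 4 + np.linalg.inv(K),
                                 (yt - X @ beta) / 4)
        np.testing.assert_allclose(b, oracle, atol=1e-8)


def _random_instance(rng, n=40, p=12, m=2, tau=0.8):
    X = np.column_stack([np.ones(n), rng.normal(size=(n, m - 1))])
    G = rng.normal(size=(n, p))
    V = random_psd(rng, n)
    y = rng.binomial(1, 0.5, n).astype(float)
    km = eigendecompose([V], [tau])
    Xfull = np.column_stack([X, G])
    v = default_penalty_factors(m, p)
    rs = build_rotated(None, km, Xfull)
    return rs, km, Xfull, y, v, m, p


class TestLambdaGrid:
    def test_empty_then_nonempty_active_set(self, fitted_glmm):
        fit = fitted_glmm["fit"]
        assert fit.n_active[0] == 0
        # refit at 0.99 lambda_max: at least one SNP enters
        spec = PenaltySpec(lambdas=np.array([0.99 * fit.lambdas[0]]),
                           penalty_factors=fit.penalty_factors)
        fit2 = cd_fit(fitted_glmm["rs"], fitted_glmm["y"], spec,
                      fitted_glmm["null"])
        assert fit2.n_active[0] >= 1

    def test_doubling_weights_halves_lambda_max(self, rng):
        rs, km, Xfull, y, v, m, p = _random_instance(rng)
        spec1 = PenaltySpec(penalty_factors=v)
        spec2 = PenaltySpec(penalty_factors=np.where(v > 0, 2.0 * v, 0.0))
        g1 = lambda_grid(rs, spec1, None, y)
        g2 = lambda_grid(rs, spec2, None, y)
        assert g2[0] == pytest.approx(g1[0] / 2, rel=1e-10)

    def test_all_zero_penalty_rejected(self, rng):
        rs, km, Xfull, y, v, m, p = _random_instance(rng)
        with pytest.raises(ValueError, match="penalize"):
            lambda_grid(rs, PenaltySpec(penalty_factors=np.zeros(m + p)),
                        None, y)


class TestCdFit:
    def test_matches_proximal_gradient_oracle(self, rng):
        # independent FISTA minimizer of the exact objective, 2 instances
        for _ in range(2):
            rs, km, Xfull, y, v, m, p = _random_instance(rng, n=30, p=10)
            spec = PenaltySpec(nlambda=6, lambda_min_ratio=0.05,
                               penalty_factors=v)
            fit = cd_fit(rs, y, spec, None, outer_tol=1e-13, max_outer=5000,
                         inner_tol=1e-10, max_sweeps=20000)
            for k in (1, 3, 5):
                beta_o, b_o, obj_o = fista_pql(Xfull, y, rs.d, km.U, v,
                                               fit.lambdas[k])
                np.testing.assert_allclose(fit.coef[:, k], beta_o, atol=1e-5)
                obj_cd = pql_objective(Xfull, y, rs.d, km.U, v,
                                       fit.lambdas[k], fit.coef[:, k],
                                       fit.b_prof[:, k])
                assert obj_cd <= obj_o + 1e-8

    def test_tau_zero_reduces_to_logistic_lasso(self, rng):
        # with K = 0 the method IS a bound-based penalized logistic model
        n, p, m = 100, 30, 2
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        G = rng.normal(size=(n, p))
        beta_true = np.zeros(p)
        beta_true[:3] = [0.8, -0.8, 0.6]
        eta = X @ [-0.3, 0.5] + G @ beta_true
        y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
        km0 = eigendecompose([np.eye(n)], [0.0])
        Xfull = np.column_stack([X, G])
        v = default_penalty_factors(m, p)
        rs = build_rotated(None, km0, Xfull)
        spec = PenaltySpec(nlambda=8, lambda_min_ratio=0.05, penalty_factors=v)
        fit = cd_fit(rs, y, spec, None, outer_tol=1e-13, max_outer=5000,
                     inner_tol=1e-10, max_sweeps=20000)
        for k in (2, 5, 7):
            beta_o, _, _ = fista_pql(Xfull, y, np.zeros(n), np.eye(n), v,
                                     fit.lambdas[k])
            np.testing.assert_allclose(fit.coef[:, k], beta_o, atol=1e-5)

    def test_near_zero_penalty_approaches_mle(self, rng):
        # p=3 << n, tiny lambda: coefficients near the unpenalized logistic fit
        n, p = 200, 3
        X = np.ones((n, 1))
        G = rng.normal(size=(n, p))
        eta = -0.2 + G @ [0.7, -0.5, 0.4]
        y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
        km0 = eigendecompose([np.eye(n)], [0.0])
        Xfull = np.column_stack([X, G])
        v = default_penalty_factors(1, p)
        rs = build_rotated(None, km0, Xfull)
        spec0 = PenaltySpec(penalty_factors=v)
        lam_max = lambda_grid(rs, spec0, None, y)[0]
        spec = PenaltySpec(lambdas=np.array([1e-4 * lam_max]),
                           penalty_factors=v)
        fit = cd_fit(rs, y, spec, None, outer_tol=1e-13, max_outer=5000,
                     inner_tol=1e-10)
        glm = sm.GLM(y, Xfull, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.coef[:, 0], glm.params, rtol=0.02)

    def test_gaussian_family_matches_dense_lmm_oracle(self, rng):
        n, p, m = 40, 10, 2
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        G = rng.normal(size=(n, p))
        V = random_psd(rng, n)
        tau = 1.2
        y = X @ [0.5, -0.4] + G[:, 0] * 0.8 + \
            np.linalg.cholesky(np.eye(n) + tau * V) @ rng.normal(size=n)
        km = eigendecompose([V], [tau])
        Xfull = np.column_stack([X, G])
        v = default_penalty_factors(m, p)
        rs = build_rotated(None, km, Xfull, family="gaussian")
        spec = PenaltySpec(nlambda=6, lambda_min_ratio=0.05, penalty_factors=v)
        fit = cd_fit(rs, y, spec, None, outer_tol=1e-14, max_outer=500,
                     inner_tol=1e-12, max_sweeps=50000)
        Sigma = np.eye(n) + tau * V
        for k in (1, 3, 5):
            beta_o, _ = gaussian_pen_lmm_oracle(Xfull, y, Sigma, v,
                                                fit.lambdas[k])
            np.testing.assert_allclose(fit.coef[:, k], beta_o, atol=1e-6)

    def test_kkt_conditions_hold_along_path(self, fitted_glmm):
        viol = kkt_violation(fitted_glmm["fit"], fitted_glmm["rs"])
        assert viol.max() < 1e-6

    def test_surrogate_objective_decreases_per_sweep(self, rng):
        # the weighted quadratic the CD minimizes never increases
        rs, km, Xfull, y, v, m, p = _random_instance(rng, n=25, p=8)
        lam = 0.05
        Xs = np.asfortranarray(rs.Xstar)
        Xw = np.asfortranarray(Xs * rs.w[:, None])
        colnorm = np.einsum("ij,ij->j", Xw, Xs)
        yt = rng.normal(size=25) * 2
        ystar = rs.U.T @ yt
        beta = np.zeros(m + p)
        r = ystar - Xs @ beta
        lamv = lam * v

        def quad():
            return 0.5 * np.sum(rs.w * r**2) + np.sum(lamv * np.abs(beta))

        prev = quad()
        for _ in range(30):
            cd_sweeps(Xw, Xs, r, beta, lamv, colnorm, 0.0, 1)
            cur = quad()
            assert cur <= prev + 1e-10
            prev = cur

    def test_path_continuity_in_lambda(self, fitted_glmm):
        # refine the grid between two path points: solutions interpolate
        fit, rs = fitted_glmm["fit"], fitted_glmm["rs"]
        k = min(10, fit.n_lambda - 2)
        lams = np.geomspace(fit.lambdas[k], fit.lambdas[k + 1], 8)
        spec = PenaltySpec(lambdas=lams, penalty_factors=fit.penalty_factors)
        fine = cd_fit(rs, fitted_glmm["y"], spec, fitted_glmm["null"])
        steps = np.abs(np.diff(fine.coef, axis=1)).max(axis=0)
        assert steps.max() < 0.15  # small coefficient motion on a fine grid

    def test_max_active_truncates_path(self, fitted_glmm):
        spec = PenaltySpec(nlambda=25, lambda_min_ratio=0.05,
                           penalty_factors=fitted_glmm["fit"].penalty_factors)
        fit = cd_fit(fitted_glmm["rs"], fitted_glmm["y"], spec,
                     fitted_glmm["null"], max_active=5)
        assert fit.n_lambda < 25
        assert (fit.n_active[:-1] <= 5).all()


class TestAdaptiveWeights:
    def test_kappa_zero_is_unit_weights(self, rng):
        G = rng.normal(size=(40, 6))
        X = np.ones((40, 1))
        y = rng.binomial(1, 0.5, 40).astype(float)
        np.testing.assert_array_equal(adaptive_weights(G, X, y, 0.0),
                                      np.ones(6))

    def test_matches_statsmodels_marginal_fits(self, rng):
        n, p = 300, 5
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        G = rng.normal(size=(n, p))
        eta = -0.5 + G[:, 0] * 0.9
        y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
        v = adaptive_weights(G, X, y, kappa=1.0)
        for j in range(p):
            D = np.column_stack([X, G[:, j]])
            bj = sm.GLM(y, D, family=sm.families.Binomial()).fit().params[-1]
            assert v[j] == pytest.approx(abs(bj) ** -1.0, rel=1e-4)

    def test_power_scaling(self, rng):
        n, p = 200, 4
        X = np.ones((n, 1))
        G = rng.normal(size=(n, p))
        y = rng.binomial(1, 1 / (1 + np.exp(-G[:, 0])), n).astype(float)
        v1 = adaptive_weights(G, X, y, kappa=1.0)
        v2 = adaptive_weights(G, X, y, kappa=2.0)
        np.testing.assert_allclose(v2, v1**2, rtol=1e-6)

    def test_causal_snp_gets_smaller_weight(self):
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            n, p = 250, 20
            X = np.ones((n, 1))
            G = rng.normal(size=(n, p))
            eta = -0.5 + 1.2 * G[:, 0]  # SNP 0 strongly causal
            y = rng.binomial(1, 1 / (1 + np.exp(-eta))).astype(float)
            v = adaptive_weights(G, X, y, kappa=1.0)
            hits += v[0] < np.median(v[1:])
        assert hits >= 8
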