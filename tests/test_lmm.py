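"""Eigen-rotated FIML mixed model against direct N x N oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import multivariate_normal

from triomr import EigenLMM, LMMFit, fit_fiml, lrt, rotate


def _random_grm(n, m, rng):
    z = rng.standard_normal((n, m))
    A = z @ z.T / m
    d, U = np.linalg.eigh(A)
    order = np.argsort(d)[::-1]
    return A, np.clip(d[order], 0, None), U[:, order]


def _mvn_data(n, A, sg2, se2, rng, p=2):
    X = rng.standard_normal((n, p))
    beta = rng.normal(0, 0.5, p)
    L = np.linalg.cholesky(A * sg2 + np.eye(n) * se2 + 1e-10 * np.eye(n))
    y = 0.7 + X @ beta + L @ rng.standard_normal(n)
    return y, X


def _direct_loglik(y, Xd, A, beta, sg2, se2):
    S = A * sg2 + np.eye(len(y)) * se2
    return multivariate_normal.logpdf(y, mean=Xd @ beta, cov=S,
                                      allow_singular=True)


class TestRotation:
    def test_rotation_is_invertible(self, rng):
        _, d, U = _random_grm(30, 100, rng)
        y = rng.standard_normal(30)
        X = rng.standard_normal((30, 2))
        ystar, Xstar = rotate(y, X, U)
        assert np.abs(U @ ystar - y).max() < 1e-10
        assert np.abs(U @ Xstar - X).max() < 1e-10

    def test_loglik_matches_direct_density_at_fixed_parameters(self, rng):
        """Rotated factorized likelihood equals the N x N multivariate
        normal density at arbitrary parameter values."""
        n = 50
        A, d, U = _random_grm(n, 300, rng)
        y, X = _mvn_data(n, A, 0.4, 0.6, rng)
        Xd = np.column_stack([np.ones(n), X])
        for sg2, se2 in [(0.4, 0.6), (0.05, 1.2), (1.5, 0.3)]:
            beta = rng.normal(0, 0.5, 3)
            direct = _direct_loglik(y, Xd, A, beta, sg2, se2)
            ystar, Xstar = rotate(y, Xd, U)
            v = d * sg2 + se2
            rotated = -0.5 * np.sum(np.log(2 * np.pi * v)
                                    + (ystar - Xstar @ beta) ** 2 / v)
            assert abs(direct - rotated) < 1e-6

    def test_maximized_loglik_matches_brute_force_fiml(self, rng):
        """Profile-search optimum agrees with a generic optimizer on the
        direct N x N likelihood."""
        n = 50
        A, d, U = _random_grm(n, 300, rng)
        y, X = _mvn_data(n, A, 0.4, 0.6, rng)
        fit = fit_fiml(y, X, eigenvalues=d, eigenvectors=U)
        Xd = np.column_stack([np.ones(n), X])

        def nll(par):
            return -_direct_loglik(y, Xd, A, par[:3], np.exp(par[3]),
                                   np.exp(par[4]))

        start = np.r_[fit.beta, np.log(max(fit.sigma_g2, 1e-6)),
                      np.log(fit.sigma_e2)]
        res = minimize(nll, start, method="Nelder-Mead",
                       options={"maxiter": 50_000, "xatol": 1e-12,
                                "fatol": 1e-12})
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-4)
        assert fit.loglik >= -res.fun - 1e-4   # never below the oracle max


class TestFit:
    def test_independence_limit_matches_ols(self, rng):
        """Under A = I the genetic/residual split is unidentifiable and
        the fit reduces exactly to OLS."""
        n = 200
        X = rng.standard_normal((n, 2))
        y = 1.0 + X @ np.array([0.3, -0.2]) + rng.standard_normal(n)
        fit = fit_fiml(y, X)
        Xd = np.column_stack([np.ones(n), X])
        beta_ols, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        resid = y - Xd @ beta_ols
        sigma2 = resid @ resid / n
        se_ols = np.sqrt(np.diag(np.linalg.inv(Xd.T @ Xd)) * sigma2)
        assert np.abs(fit.beta - beta_ols).max() < 1e-10
        assert np.abs(fit.se - se_ols).max() < 1e-10
        assert not fit.identifiable
        assert fit.sigma_g2 == 0.0

    def test_variance_components_recovered_in_sibships(self, rng):
        """(sigma_g2, sigma_e2) = (0.4, 0.6) recovered without systematic
        bias in a cohort of 1000 full-sib pairs."""
        n_pairs, n = 1000, 2000
        # analytic eigenstructure of a full-sib block-diagonal GRM
        blocks_d = np.concatenate([np.full(n_pairs, 1.5),
                                   np.full(n_pairs, 0.5)])
        U = np.zeros((n, n))
        s = 1 / np.sqrt(2)
        for k in range(n_pairs):
            U[2 * k, k], U[2 * k + 1, k] = s, s
            U[2 * k, n_pairs + k], U[2 * k + 1, n_pairs + k] = s, -s
        sg_hat, se_hat = [], []
        for seed in range(6):
            r = np.random.default_rng(seed)
            X = r.standard_normal((n, 2))
            scale = np.sqrt(blocks_d * 0.4 + 0.6)
            y = 0.5 + X @ np.array([0.2, -0.1]) \
                + U @ (scale * r.standard_normal(n))
            fit = fit_fiml(y, X, eigenvalues=blocks_d, eigenvectors=U)
            sg_hat.append(fit.sigma_g2)
            se_hat.append(fit.sigma_e2)
        for est, truth in [(sg_hat, 0.4), (se_hat, 0.6)]:
            mc_se = np.std(est, ddof=1) / np.sqrt(len(est))
            assert abs(np.mean(est) - truth) < 3 * mc_se + 0.01

    def test_permutation_invariance(self, rng):
        n = 80
        A, d, U = _random_grm(n, 200, rng)
        y, X = _mvn_data(n, A, 0.3, 0.7, rng)
        fit = fit_fiml(y, X, eigenvalues=d, eigenvectors=U)
        perm = rng.permutation(n)
        Ap = A[np.ix_(perm, perm)]
        dp, Up = np.linalg.eigh(Ap)
        order = np.argsort(dp)[::-1]
        fit_p = fit_fiml(y[perm], X[perm], eigenvalues=np.clip(
            dp[order], 0, None), eigenvectors=Up[:, order])
        assert np.abs(fit.beta - fit_p.beta).max() < 1e-8
        # variance components absorb eigh round-off from two independent
        # decompositions; 1e-7 is the attainable agreement
        assert fit.sigma_g2 == pytest.approx(fit_p.sigma_g2, abs=1e-7)
        assert fit.loglik == pytest.approx(fit_p.loglik, abs=1e-8)

    def test_eigenvector_sign_flip_is_irrelevant(self, rng):
        n = 60
        A, d, U = _random_grm(n, 200, rng)
        y, X = _mvn_data(n, A, 0.3, 0.7, rng)
        fit = fit_fiml(y, X, eigenvalues=d, eigenvectors=U)
        flip = U * np.where(rng.random(n) < 0.5, -1.0, 1.0)
        fit_f = fit_fiml(y, X, eigenvalues=d, eigenvectors=flip)
        assert fit.loglik == pytest.approx(fit_f.loglik, abs=1e-10)
        assert np.abs(fit.beta - fit_f.beta).max() < 1e-10

    def test_sklearn_estimator_interface(self, rng):
        n = 100
        X = rng.standard_normal((n, 2))
        y = X @ np.array([0.5, -0.5]) + rng.standard_normal(n)
        est = EigenLMM().fit(X, y)
        assert est.coef_.shape == (2,)
        assert est.predict(X).shape == (n,)
        params = est.get_params()
        assert EigenLMM(**params).get_params() == params
        r = est.result()
        assert r.n == n

    def test_rank_deficient_design_rejected(self, rng):
        X = np.ones((50, 2))
        with pytest.raises(ValueError):
            fit_fiml(rng.standard_normal(50), X)


class TestLRT:
    def test_identical_models_give_stat_zero(self):
        fit = LMMFit(beta=np.zeros(1), se=np.ones(1), sigma_g2=0.1,
                     sigma_e2=0.9, loglik=-12.3, converged=True, n_iter=5,
                     n=10)
        res = lrt(fit, fit)
        assert res.stat == 0.0
        assert res.p == 1.0

    def test_chi_square_quantile_identity(self):
        full = LMMFit(np.zeros(1), np.ones(1), 0.1, 0.9, -10.0, True, 1, 10)
        sub = LMMFit(np.zeros(1), np.ones(1), 0.1, 0.9,
                     -10.0 - 3.841458820694124 / 2, True, 1, 10)
        assert lrt(full, sub).p == pytest.approx(0.05, abs=1e-9)

    def test_non_nested_models_rejected(self):
        full = LMMFit(np.zeros(1), np.ones(1), 0.1, 0.9, -12.0, True, 1, 10)
        sub = LMMFit(np.zeros(1), np.ones(1), 0.1, 0.9, -11.0, True, 1, 10)
        with pytest.raises(ValueError):
            lrt(full, sub)

    def test_covariate_rescaling_leaves_lrt_unchanged(self, rng):
        """An affine rescale of a covariate rescales its beta but leaves
        the likelihood-ratio statistic unchanged."""
        n = 120
        A, d, U = _random_grm(n, 200, rng)
        y, X = _mvn_data(n, A, 0.3, 0.7, rng)
        full = fit_fiml(y, X, eigenvalues=d, eigenvectors=U)
        sub = fit_fiml(y, X[:, 1:], eigenvalues=d, eigenvectors=U)
        stat = lrt(full, sub).stat

        X2 = X.copy()
        X2[:, 0] = 10 * X2[:, 0] + 3
        full2 = fit_fiml(y, X2, eigenvalues=d, eigenvectors=U)
        stat2 = lrt(full2, sub).stat
        assert stat2 == pytest.approx(stat, abs=1e-6)
        assert full2.beta[1] == pytest.approx(full.beta[1] / 10, rel=1e-6)
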