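"""Two-variance-component FIML linear mixed model via spectral rotation.

The model is y ~ N(X beta, Sigma) with Sigma = A sigma_g^2 + I sigma_e^2,
where A is a genetic relationship matrix over the analysis individuals.
Writing A = U diag(d) U' and premultiplying y and X by U' "rotates away"
the dependence between observations: the rotated observation i has
independent variance v_i = d_i sigma_g^2 + sigma_e^2, so the multivariate-
normal likelihood factorizes over individuals and no N x N matrix is ever
inverted.  Exactly two variance components are fitted, one of them a
residual component that is uncorrelated across individuals.

Estimation is full-information maximum likelihood (ML, not REML, so that
log-likelihoods are comparable across fixed-effect specifications):
given the variance ratio delta = sigma_g^2 / sigma_e^2, beta is the
weighted-least-squares solution with weights 1/(d_i delta + 1) and
sigma_e^2 is profiled out in closed form; a 1-D search over log(delta)
(coarse bracketing grid refined by bounded minimization) completes the
optimization.  Fixed effects are tested by likelihood-ratio chi-square
against a sub-model with the relevant parameter fixed at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = ["EigenLMM", "LMMFit", "LRTResult", "rotate", "fit_fiml", "lrt"]


@dataclass
class LMMFit:
    """Fitted fixed effects and variance components."""

    beta: np.ndarray
    se: np.ndarray
    sigma_g2: float
    sigma_e2: float
    loglik: float
    converged: bool
    n_iter: int
    n: int
    identifiable: bool = True

    @property
    def h2(self) -> float:
        """Fraction of phenotypic variance attributed to the GRM."""
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)


@dataclass
class LRTResult:
    stat: float
    df: int
    p: float


def rotate(y: np.ndarray, X: np.ndarray, U: np.ndarray
           ) -> tuple[np.ndarray, np.ndarray]:
    """Premultiply outcome and design by the eigenvector matrix transpose."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.shape[0] != X.shape[0] or U.shape[0] != y.shape[0]:
        raise ValueError("dimension mismatch between y, X and U")
    return U.T @ y, U.T @ X


def _profile_nll(log_delta: float, ystar: np.ndarray, Xstar: np.ndarray,
                 d: np.ndarray) -> float:
    """-2 log-likelihood profiled over beta and sigma_e^2 at fixed delta."""
    n = len(ystar)
    delta = np.exp(log_delta)
    v = d * delta + 1.0
    w = 1.0 / v
    Xw = Xstar * w[:, None]
    beta, *_ = np.linalg.lstsq(Xw.T @ Xstar, Xw.T @ ystar, rcond=None)
    resid = ystar - Xstar @ beta
    rss_w = float(resid @ (w * resid))
    sigma_e2 = rss_w / n
    return n * np.log(2 * np.pi * sigma_e2) + n + float(np.log(v).sum())


def _wls(ystar: np.ndarray, Xstar: np.ndarray, w: np.ndarray
         ) -> tuple[np.ndarray, np.ndarray, float]:
    Xw = Xstar * w[:, None]
    xtx = Xw.T @ Xstar
    beta = np.linalg.solve(xtx, Xw.T @ ystar)
    resid = ystar - Xstar @ beta
    rss_w = float(resid @ (w * resid))
    return beta, np.linalg.inv(xtx), rss_w


class EigenLMM(RegressorMixin, BaseEstimator):
    """Linear mixed model y ~ N(X beta, A sigma_g^2 + I sigma_e^2).

    Parameters
    ----------
    grid : int
        Number of points in the coarse log-variance-ratio bracketing grid.
    log_delta_range : tuple of float
        Search range for log(sigma_g^2 / sigma_e^2).
    tol : float
        Relative log-likelihood convergence tolerance of the 1-D refine
        step.
    fit_intercept : bool
        Prepend a column of ones to X.

    The relatedness structure is passed to :meth:`fit` either as a
    pre-computed eigendecomposition ``(eigenvectors, eigenvalues)`` or as a
    dense symmetric matrix ``A``; with neither, observations are treated
    as independent (A = I, in which case the genetic/residual split is
    unidentifiable and only the total variance is reported, with
    ``identifiable_ = False``).

    Attributes (after fit): ``beta_``, ``se_``, ``sigma_g2_``,
    ``sigma_e2_``, ``loglik_``, ``converged_``, ``n_iter_``,
    ``identifiable_``, and sklearn's ``coef_`` / ``intercept_`` aliases.
    """

    def __init__(self, grid: int = 33,
                 log_delta_range: tuple[float, float] = (-8.0, 8.0),
                 tol: float = 1e-10, fit_intercept: bool = True):
        self.grid = grid
        self.log_delta_range = log_delta_range
        self.tol = tol
        self.fit_intercept = fit_intercept

    # -- sklearn API -----------------------------------------------------
    def fit(self, X, y, A: np.ndarray | None = None,
            eigenvectors: np.ndarray | None = None,
            eigenvalues: np.ndarray | None = None) -> "EigenLMM":
        X = check_array(X, ensure_2d=True)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != X.shape[0]:
            raise ValueError("X and y have different numbers of rows")
        if self.fit_intercept:
            X = np.column_stack([np.ones(len(y)), X])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient")

        if eigenvalues is None and A is not None:
            if not np.allclose(A, A.T, atol=1e-8):
                raise ValueError("A must be symmetric")
            eigenvalues, eigenvectors = np.linalg.eigh(A)
            eigenvalues = np.clip(eigenvalues, 0.0, None)
        if eigenvalues is None:
            # independence: rotation is the identity
            eigenvalues = np.ones(len(y))
            ystar, Xstar = y, X
        elif eigenvectors is None:
            raise ValueError("eigenvalues given without eigenvectors")
        else:
            ystar, Xstar = rotate(y, X, eigenvectors)
        d = np.asarray(eigenvalues, dtype=float)
        if len(d) != len(y):
            raise ValueError("eigenvalue count does not match sample size")

        n = len(y)
        identifiable = bool(np.ptp(d) > 1e-12)
        if not identifiable:
            # A proportional to I: only the total variance is estimable
            scale = float(d.mean()) if d.mean() > 0 else 1.0
            beta, xtx_inv, rss = _wls(ystar, Xstar, np.ones(n))
            sigma = rss / n
            loglik = -0.5 * (n * np.log(2 * np.pi * sigma) + n)
            self._store(X, beta, np.sqrt(np.diag(xtx_inv) * sigma),
                        0.0, sigma * scale, loglik, True, 1, n, False)
            return self

        lo, hi = self.log_delta_range
        grid = np.linspace(lo, hi, self.grid)
        nll = np.array([_profile_nll(g, ystar, Xstar, d) for g in grid])
        # boundary candidate sigma_g2 = 0 (delta effectively zero)
        nll0 = _profile_nll(-50.0, ystar, Xstar, d)
        best = int(np.argmin(nll))
        n_iter = self.grid + 1
        if nll0 <= nll.min():
            log_delta, best_nll, converged = -np.inf, nll0, True
        else:
            a = grid[max(best - 1, 0)]
            b = grid[min(best + 1, self.grid - 1)]
            res = optimize.minimize_scalar(
                _profile_nll, args=(ystar, Xstar, d), bounds=(a, b),
                method="bounded",
                options={"xatol": 1e-12, "maxiter": 1000})
            n_iter += int(res.nfev)
            if res.fun <= nll[best]:
                log_delta, best_nll = float(res.x), float(res.fun)
            else:
                log_delta, best_nll = float(grid[best]), float(nll[best])
            converged = bool(res.success)

        delta = np.exp(log_delta) if np.isfinite(log_delta) else 0.0
        v = d * delta + 1.0
        w = 1.0 / v
        beta, xtx_inv, rss_w = _wls(ystar, Xstar, w)
        sigma_e2 = rss_w / n
        sigma_g2 = delta * sigma_e2
        se = np.sqrt(np.diag(xtx_inv) * sigma_e2)
        loglik = -0.5 * best_nll
        self._store(X, beta, se, sigma_g2, sigma_e2, loglik, converged,
                    n_iter, n, True)
        return self

    @property
    def _n(self) -> int:
        return getattr(self, "_n_samples", 0)

    def _store(self, X, beta, se, sg2, se2, loglik, converged, n_iter, n,
               identifiable):
        self._n_samples = n
        self.beta_ = beta
        self.se_ = se
        self.sigma_g2_ = float(sg2)
        self.sigma_e2_ = float(se2)
        self.loglik_ = float(loglik)
        self.converged_ = converged
        self.n_iter_ = n_iter
        self.identifiable_ = identifiable
        self.n_features_in_ = X.shape[1] - (1 if self.fit_intercept else 0)
        if self.fit_intercept:
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:]
        else:
            self.intercept_ = 0.0
            self.coef_ = beta

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "beta_")
        X = check_array(X, ensure_2d=True)
        return self.intercept_ + X @ self.coef_

    def result(self) -> LMMFit:
        check_is_fitted(self, "beta_")
        return LMMFit(beta=self.beta_, se=self.se_, sigma_g2=self.sigma_g2_,
                      sigma_e2=self.sigma_e2_, loglik=self.loglik_,
                      converged=self.converged_, n_iter=self.n_iter_,
                      n=self._n, identifiable=self.identifiable_)


def fit_fiml(y: np.ndarray, X: np.ndarray,
             eigenvalues: np.ndarray | None = None,
             eigenvectors: np.ndarray | None = None,
             A: np.ndarray | None = None,
             fit_intercept: bool = True, **kwargs) -> LMMFit:
    """Functional wrapper over :class:`EigenLMM`."""
    est = EigenLMM(fit_intercept=fit_intercept, **kwargs)
    est.fit(X, y, A=A, eigenvectors=eigenvectors, eigenvalues=eigenvalues)
    fit = LMMFit(beta=est.beta_, se=est.se_, sigma_g2=est.sigma_g2_,
                 sigma_e2=est.sigma_e2_, loglik=est.loglik_,
                 converged=est.converged_, n_iter=est.n_iter_,
                 n=len(np.asarray(y).ravel()),
                 identifiable=est.identifiable_)
    return fit


def lrt(full: LMMFit, sub: LMMFit, df: int = 1) -> LRTResult:
    """Likelihood-ratio test of a sub-model nested in the full model."""
    stat = -2.0 * (sub.loglik - full.loglik)
    if stat < -1e-6:
        raise ValueError(
            f"sub-model log-likelihood exceeds the full model's by "
            f"{-stat:.3g}: models are not nested or the optimizer failed")
    stat = max(stat, 0.0)
    return LRTResult(stat=stat, df=df, p=float(stats.chi2.sf(stat, df)))
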