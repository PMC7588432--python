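"""Analytic power for conditional parent/offspring GRS tests and the
standardized path-model variance algebra.

The conditional test regresses a standardized offspring outcome on a
tested GRS while adjusting for a conditioning GRS correlated ``r_cond``
with it (0.5 for a parent-offspring pair under random mating).  For a
tested GRS explaining a marginal fraction ``q2`` of outcome variance, the
1-df likelihood-ratio/Wald chi-square has noncentrality

    ncp = n * q2 * (1 - r_cond**2),

the (1 - r^2) factor being the collinearity penalty for conditioning.
Power is the probability that a noncentral chi-square(1, ncp) exceeds the
central chi-square critical value at the two-sided alpha.

The path algebra works on the standardized single-latent-factor model:
maternal GRS -> latent intrauterine factor (gamma), factor -> birthweight
(lambda1), factor -> outcome (lambda2), residual birthweight-outcome
covariance theta.  The variance of birthweight explained by the maternal
GRS is gamma^2 lambda1^2, the variance of the outcome explained is
gamma^2 lambda2^2, and the implied birthweight-outcome correlation is
lambda1 lambda2 + theta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "PowerQuery", "PathModel",
    "power_conditional_grs", "min_detectable_variance",
    "gamma_from_bw_variance", "outcome_variance_explained",
    "implied_bw_outcome_correlation", "power_by_simulation",
]


@dataclass
class PowerQuery:
    """Inputs of the conditional-GRS power calculation."""

    n: int                  # complete parent-offspring pairs
    q2: float               # marginal outcome variance explained by the GRS
    alpha: float = 0.05     # two-sided type-I error rate
    r_cond: float = 0.5     # corr(tested GRS, conditioning GRS)

    def validate(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not 0.0 <= self.q2 < 1.0:
            raise ValueError("q2 must lie in [0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not -1.0 < self.r_cond < 1.0:
            raise ValueError("r_cond must lie in (-1, 1)")


@dataclass
class PathModel:
    """Standardized path coefficients of the latent intrauterine model."""

    gamma: float
    lambda1: float
    lambda2: float
    theta: float = 0.0

    def validate(self) -> None:
        for name in ("gamma", "lambda1", "lambda2"):
            if abs(getattr(self, name)) > 1.0:
                raise ValueError(f"{name}^2 must not exceed 1 on the "
                                 "standardized scale")


def power_conditional_grs(q: PowerQuery | None = None, *, n: int | None = None,
                          q2: float | None = None, alpha: float = 0.05,
                          r_cond: float = 0.5) -> float:
    """Asymptotic power of the 1-df conditional GRS test."""
    if q is None:
        q = PowerQuery(n=n, q2=q2, alpha=alpha, r_cond=r_cond)
    q.validate()
    crit = stats.chi2.ppf(1.0 - q.alpha, 1)
    ncp = q.n * q.q2 * (1.0 - q.r_cond ** 2)
    if ncp == 0.0:
        return q.alpha
    return float(stats.ncx2.sf(crit, 1, ncp))


def min_detectable_variance(n: int, alpha: float = 0.05,
                            target_power: float = 0.80,
                            r_cond: float = 0.5,
                            rtol: float = 1e-8) -> float:
    """Smallest marginal variance fraction q2 reaching ``target_power``."""
    if not alpha < target_power < 1.0:
        raise ValueError("target_power must lie in (alpha, 1)")
    if target_power <= alpha:
        return 0.0

    def gap(q2: float) -> float:
        return power_conditional_grs(PowerQuery(n, q2, alpha, r_cond)) \
            - target_power

    hi = 1e-6
    while gap(hi) < 0 and hi < 0.5:
        hi *= 2
    sol = optimize.brentq(gap, 0.0, hi, rtol=rtol)
    return float(sol)


def gamma_from_bw_variance(q2_bw: float, lambda1: float) -> float:
    """GRS-to-factor path implied by the maternal GRS explaining ``q2_bw``
    of birthweight variance: gamma = sqrt(q2_bw / lambda1^2)."""
    if lambda1 == 0:
        raise ValueError("gamma is undefined when lambda1 = 0")
    return float(np.sqrt(q2_bw / lambda1 ** 2))


def outcome_variance_explained(p: PathModel) -> float:
    """Fraction of outcome variance explained by the maternal GRS:
    gamma^2 * lambda2^2."""
    p.validate()
    return float(p.gamma ** 2 * p.lambda2 ** 2)


def implied_bw_outcome_correlation(p: PathModel) -> float:
    """Model-implied birthweight-outcome correlation lambda1*lambda2 +
    theta; raises if the model is inconsistent (|r| > 1)."""
    p.validate()
    r = p.lambda1 * p.lambda2 + p.theta
    if abs(r) > 1.0:
        raise ValueError("implied correlation outside [-1, 1]: "
                         "inconsistent path model")
    return float(r)


def power_by_simulation(q: PowerQuery, n_reps: int = 500,
                        seed: int = 0) -> tuple[float, float]:
    """Monte-Carlo oracle for :func:`power_conditional_grs`.

    Simulates ``n_reps`` conditional regressions: bivariate-normal
    (tested, conditioning) regressors with correlation ``r_cond``, an
    outcome carrying a marginal effect scaled to ``q2``, and a Wald
    chi-square on the tested coefficient.  Returns (rejection fraction,
    binomial SE).
    """
    if n_reps < 100:
        raise ValueError("n_reps must be at least 100")
    q.validate()
    rng = np.random.default_rng(seed)
    b = np.sqrt(q.q2)
    crit = stats.chi2.ppf(1.0 - q.alpha, 1)
    rejections = 0
    for _ in range(n_reps):
        g = rng.standard_normal((q.n, 2))
        g[:, 1] = q.r_cond * g[:, 0] + np.sqrt(1 - q.r_cond ** 2) * g[:, 1]
        y = b * g[:, 0] + np.sqrt(max(1.0 - q.q2, 0.0)) \
            * rng.standard_normal(q.n)
        X = np.column_stack([np.ones(q.n), g])
        xtx_inv = np.linalg.inv(X.T @ X)
        beta = xtx_inv @ (X.T @ y)
        resid = y - X @ beta
        sigma2 = resid @ resid / q.n       # ML scale, matching the LRT
        wald = beta[1] ** 2 / (xtx_inv[1, 1] * sigma2)
        rejections += wald > crit
    p_hat = rejections / n_reps
    return float(p_hat), float(np.sqrt(p_hat * (1 - p_hat) / n_reps))
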