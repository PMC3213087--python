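"""Closed-form Gaussian computations with regression coefficients integrated out.

With a conjugate normal prior beta ~ N(m, V) and Gaussian response
y | beta ~ N(X beta, Sigma), the coefficients integrate out analytically:

    p(y | M_k, theta) = N(y; X_k m_k, X_k V_k X_k' + Sigma(theta)),

which is what makes the partial-analytic reversible-jump move possible —
model proposals are accepted on the ratio of these marginals times the model
prior, with no coefficient proposal.  The same algebra gives the coefficient
full conditional used in the Gibbs step,

    beta | y, M_k, theta ~ N(B b, B),
    B = (X' Sigma^-1 X + V^-1)^-1,  b = X' Sigma^-1 y + V^-1 m.

All dense solves go through Cholesky factorizations; the only explicit
inverse is V^-1 of the (small, typically diagonal) prior covariance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.linalg import cho_solve, solve_triangular

from .covariance import cholesky_with_jitter
from .model_space import ModelIndicator, ModelPrior, log_model_prior

__all__ = [
    "CoefficientPrior",
    "integrated_log_likelihood",
    "log_conditional_model_posterior",
    "beta_full_conditional",
    "draw_beta",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class CoefficientPrior:
    """Normal prior N(m, V) on regression coefficients, full candidate scale."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.covariance = np.atleast_2d(np.asarray(self.covariance, dtype=float))
        p = self.mean.size
        if self.covariance.shape != (p, p):
            raise ValueError("prior covariance must be p x p matching the prior mean")
        if not np.allclose(self.covariance, self.covariance.T):
            raise ValueError("prior covariance must be symmetric")
        if p > 0:
            np.linalg.cholesky(self.covariance)  # raises if not PD

    @property
    def p(self) -> int:
        return self.mean.size

    def restrict(self, gamma: np.ndarray) -> "CoefficientPrior":
        """Sub-prior for the covariates included in a model."""
        idx = np.flatnonzero(np.asarray(gamma) == 1)
        return CoefficientPrior(self.mean[idx], self.covariance[np.ix_(idx, idx)])


def _empty_prior() -> CoefficientPrior:
    return CoefficientPrior(np.empty(0), np.empty((0, 0)))


def integrated_log_likelihood(
    y: np.ndarray,
    X: np.ndarray,
    Sigma: np.ndarray,
    prior: CoefficientPrior,
) -> float:
    """log p(y | M, theta) = log N(y; X m, X V X' + Sigma), beta integrated out.

    ``q = 0`` (no columns) is supported and means a zero-mean model.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    X = np.asarray(X, dtype=float).reshape(n, -1)
    q = X.shape[1]
    if prior.p != q:
        raise ValueError(f"design has {q} columns but prior has {prior.p} entries")
    if Sigma.shape != (n, n):
        raise ValueError("Sigma must be n x n matching y")
    if q == 0:
        mu = np.zeros(n)
        M = Sigma
    else:
        mu = X @ prior.mean
        M = X @ prior.covariance @ X.T + Sigma
    L, _ = cholesky_with_jitter(M, context="integrated-likelihood covariance")
    resid = solve_triangular(L, y - mu, lower=True)
    log_det = 2.0 * float(np.sum(np.log(np.diag(L))))
    return -0.5 * (n * _LOG_2PI + log_det + float(resid @ resid))


def log_conditional_model_posterior(
    y: np.ndarray,
    X_candidates: np.ndarray,
    model: ModelIndicator,
    Sigma: np.ndarray,
    coef_prior: CoefficientPrior,
    model_prior: ModelPrior,
) -> float:
    """Unnormalized log p(M_k | y, theta): marginal likelihood + model prior.

    Normalizing exp of this quantity over an enumerated model set yields the
    exact conditional model posterior used as the oracle for the sampler.
    """
    lp = log_model_prior(model, model_prior)
    if np.isneginf(lp):
        return -np.inf
    X_k = np.asarray(X_candidates, dtype=float)[:, model.gamma == 1]
    return integrated_log_likelihood(y, X_k, Sigma, coef_prior.restrict(model.gamma)) + lp


def beta_full_conditional(
    y: np.ndarray,
    X: np.ndarray,
    Sigma: np.ndarray,
    prior: CoefficientPrior,
) -> Tuple[np.ndarray, np.ndarray]:
    """Mean and covariance of beta | y, M, theta (conjugate normal update)."""
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    X = np.asarray(X, dtype=float).reshape(n, -1)
    q = X.shape[1]
    if q < 1:
        raise ValueError("the coefficient full conditional needs at least one column")
    if prior.p != q:
        raise ValueError(f"design has {q} columns but prior has {prior.p} entries")
    L, _ = cholesky_with_jitter(Sigma, context="residual covariance")
    Xw = solve_triangular(L, X, lower=True)
    yw = solve_triangular(L, y, lower=True)
    Lv = np.linalg.cholesky(prior.covariance)
    V_inv = cho_solve((Lv, True), np.eye(q))
    precision = Xw.T @ Xw + V_inv
    Lp = np.linalg.cholesky(precision)
    cov = cho_solve((Lp, True), np.eye(q))
    cov = 0.5 * (cov + cov.T)
    mean = cov @ (Xw.T @ yw + V_inv @ prior.mean)
    return mean, cov


def draw_beta(
    full_conditional: Tuple[np.ndarray, np.ndarray], rng: np.random.Generator
) -> np.ndarray:
    """One multivariate-normal draw from the coefficient full conditional."""
    mean, cov = full_conditional
    mean = np.asarray(mean, dtype=float).ravel()
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    if float(np.trace(cov)) == 0.0:
        return mean.copy()
    L, _ = cholesky_with_jitter(cov, context="full-conditional covariance")
    return mean + L @ rng.standard_normal(mean.size)
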