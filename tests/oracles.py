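"""Independent numerical oracles for the analytic Gaussian core.

The integrated likelihood p(y | M, theta) = E_{beta ~ N(m, V)}[N(y; X beta,
Sigma)] is recomputed here from its definition by three routes that share no
code with the package implementation:

- adaptive quadrature (scipy quad / nquad) for q <= 2,
- randomized-shift Sobol quasi-Monte Carlo over the prior for q = 3,
- tensor Gauss-Hermite on the prior measure for q <= 3 (fast cross-check).
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import nquad, quad
from scipy.special import logsumexp
from scipy.stats import multivariate_normal, qmc


def loglik_rows(y: np.ndarray, means: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    """log N(y; mu_k, Sigma) for every row mu_k of ``means``."""
    mvn = multivariate_normal(mean=np.zeros(y.size), cov=Sigma)
    return mvn.logpdf(y[None, :] - np.atleast_2d(means))


def _log_integrand_factory(y, X, Sigma, m, V):
    prior = multivariate_normal(mean=m, cov=V)

    def log_f(beta):
        beta = np.atleast_2d(beta)
        return loglik_rows(y, beta @ X.T, Sigma) + prior.logpdf(beta)

    return log_f


def log_marginal_quadrature(y, X, Sigma, m, V) -> float:
    """Adaptive quadrature of the coefficient integral (q in {0, 1, 2})."""
    y = np.asarray(y, float)
    q = X.shape[1]
    if q == 0:
        return float(multivariate_normal(mean=np.zeros(y.size), cov=Sigma).logpdf(y))
    log_f = _log_integrand_factory(y, X, Sigma, np.asarray(m, float), np.asarray(V, float))
    sd = np.sqrt(np.diag(V))
    lo = np.asarray(m, float) - 10.0 * sd
    hi = np.asarray(m, float) + 10.0 * sd
    # shift by the grid maximum so the integrand is O(1) at its peak
    grids = np.meshgrid(*[np.linspace(lo[j], hi[j], 81) for j in range(q)])
    pts = np.column_stack([g.ravel() for g in grids])
    shift = float(np.max(log_f(pts)))
    if q == 1:
        val, _ = quad(
            lambda b: float(np.exp(log_f([[b]]) - shift)),
            lo[0],
            hi[0],
            epsabs=1e-13,
            epsrel=1e-10,
            limit=200,
        )
    else:
        val, _ = nquad(
            lambda b1, b2: float(np.exp(log_f([[b1, b2]]) - shift)),
            [(lo[0], hi[0]), (lo[1], hi[1])],
            opts={"epsabs": 1e-12, "epsrel": 1e-9, "limit": 100},
        )
    return shift + float(np.log(val))


def log_marginal_qmc(y, X, Sigma, m, V, pow2: int = 17, seed: int = 202) -> float:
    """Sobol quasi-Monte Carlo estimate of E_{beta~N(m,V)}[N(y; X beta, Sigma)]."""
    y = np.asarray(y, float)
    q = X.shape[1]
    sob = qmc.Sobol(d=q, scramble=True, seed=seed)
    u = sob.random_base2(m=pow2)
    u = np.clip(u, 1e-12, 1 - 1e-12)
    from scipy.stats import norm

    Lv = np.linalg.cholesky(np.asarray(V, float))
    betas = np.asarray(m, float) + norm.ppf(u) @ Lv.T
    logs = loglik_rows(y, betas @ X.T, Sigma)
    return float(logsumexp(logs) - np.log(logs.size))


def log_marginal_gh(y, X, Sigma, m, V, nodes: int | None = None) -> float:
    """Tensor-product Gauss-Hermite integration on the prior measure (q <= 3)."""
    y = np.asarray(y, float)
    q = X.shape[1]
    if q == 0:
        return float(multivariate_normal(mean=np.zeros(y.size), cov=Sigma).logpdf(y))
    if nodes is None:
        nodes = {1: 120, 2: 80, 3: 42}.get(q, 40)
    m = np.asarray(m, float)
    V = np.asarray(V, float)
    log_f = _log_integrand_factory(y, X, Sigma, m, V)

    # centre a Gaussian reference at the integrand mode (numerical search,
    # independent of any closed-form posterior algebra) and integrate f/g
    # against it with tensor Gauss-Hermite
    from scipy.optimize import minimize

    res = minimize(lambda b: -float(log_f(b[None, :])), x0=m, method="BFGS")
    mu0 = res.x
    eps = 1e-4
    hess = np.empty((q, q))
    for i in range(q):
        for j in range(q):
            bpp = mu0.copy(); bpp[i] += eps; bpp[j] += eps
            bpm = mu0.copy(); bpm[i] += eps; bpm[j] -= eps
            bmp = mu0.copy(); bmp[i] -= eps; bmp[j] += eps
            bmm = mu0.copy(); bmm[i] -= eps; bmm[j] -= eps
            hess[i, j] = (
                float(log_f(bpp[None]) - log_f(bpm[None]) - log_f(bmp[None]) + log_f(bmm[None]))
                / (4 * eps**2)
            )
    hess = -0.5 * (hess + hess.T)
    try:
        S0 = 1.5 * np.linalg.inv(hess)
        np.linalg.cholesky(S0)
    except np.linalg.LinAlgError:
        S0 = V.copy()
    ref = multivariate_normal(mean=mu0, cov=S0)

    x, w = np.polynomial.hermite.hermgauss(nodes)
    grids = np.meshgrid(*([x] * q))
    U = np.column_stack([g.ravel() for g in grids])
    logw = np.log(w)
    wgrids = np.meshgrid(*([logw] * q))
    logW = np.sum([g.ravel() for g in wgrids], axis=0)
    L0 = np.linalg.cholesky(S0)
    betas = mu0 + np.sqrt(2.0) * U @ L0.T
    logs = log_f(betas) - ref.logpdf(betas)
    return float(logsumexp(logW + logs) - 0.5 * q * np.log(np.pi))


def random_gaussian_fixture(rng: np.random.Generator, n: int, q: int):
    """A well-scaled random (y, X, Sigma, m, V) problem for oracle comparison."""
    coords = rng.uniform(0, 4, size=(n, 2))
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    Sigma = 1.2 * np.exp(-d / 1.5) + 0.4 * np.eye(n)
    X = rng.standard_normal((n, q))
    m = rng.normal(0, 0.5, size=q)
    V = np.diag(rng.uniform(0.5, 2.5, size=q))
    beta = m + np.linalg.cholesky(V) @ rng.standard_normal(q) if q else np.zeros(0)
    y = X @ beta + np.linalg.cholesky(Sigma) @ rng.standard_normal(n)
    return y, X, Sigma, m, V
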