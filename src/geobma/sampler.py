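"""Partial-analytic reversible-jump MCMC for geostatistical regression.

One sweep of the chain updates, in order:

1-4. the spatial covariance parameters (log sill, anisotropy correlation psi,
     log ranges, log nugget) by component-wise Metropolis random walks
     (truncated-uniform proposal for psi),
5.   the model indicator gamma by a partial-analytic reversible-jump move:
     one covariate is toggled uniformly at random and the proposal is
     accepted on the ratio of conditional model posteriors
     p(M | r, theta) — available in closed form because the Gaussian layer
     integrates the coefficients out — so no coefficient proposal is needed,
6.   the coefficients beta by a Gibbs draw from their normal full
     conditional, and
7.   (Poisson family only) the latent Gaussian field z by a whole-vector
     Langevin-Hastings (MALA) step.

For the Gaussian family the response enters the analytic model move
directly; for the Poisson spatial GLMM the current latent field z plays the
role of the Gaussian response, which is what keeps the scheme family
agnostic — the spatial parameters and the latent layer are common to all
models.

Proposal scales can be auto-tuned during burn-in (targeting acceptance
around 0.35 for the random walks and 0.55 for MALA) and are frozen at the
end of burn-in, so the post-burn-in kernel is a fixed, valid MCMC kernel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from typing import Callable, Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, solve_triangular
from scipy.special import expit, gammaln

from .covariance import (
    CovarianceParams,
    NumericalDegeneracyError,
    build_covariance_matrix,
    cholesky_with_jitter,
)
from .gaussian_core import (
    CoefficientPrior,
    beta_full_conditional,
    draw_beta,
    log_conditional_model_posterior,
)
from .model_space import ModelIndicator, ModelPrior, log_model_prior, propose_model_move
from .summaries import ChainOutput

__all__ = [
    "SpatialDataset",
    "ChainState",
    "SamplerConfig",
    "log_joint",
    "update_spatial_params",
    "parj_model_update",
    "latent_log_gradient",
    "mala_update_latent",
    "run_parj",
]

logger = logging.getLogger("geobma")

_LOG_2PI = float(np.log(2.0 * np.pi))

#: latent-field values above this make exp(z) numerically meaningless
LATENT_EXP_GUARD = 30.0


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class SpatialDataset:
    """Point-referenced data: planar coordinates, candidate design, response.

    ``family`` is ``gaussian`` (response modelled directly by the spatial
    Gaussian process) or ``poisson`` (counts with log link over a latent
    Gaussian field).
    """

    coords: np.ndarray
    X: np.ndarray
    y: np.ndarray
    covariate_names: List[str]
    family: str = "gaussian"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be an n x 2 array of planar coordinates")
        n = self.coords.shape[0]
        if n < 3:
            raise ValueError(f"need at least 3 sites, got {n}")
        if self.X.shape[0] != n or self.y.shape != (n,):
            raise ValueError("coords, X and y must agree on the number of sites")
        if len(self.covariate_names) != self.X.shape[1]:
            raise ValueError("covariate_names must label every column of X")
        if len(set(self.covariate_names)) != len(self.covariate_names):
            raise ValueError("covariate names must be unique")
        for arr, what in ((self.coords, "coordinates"), (self.X, "covariates")):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{what} contain missing or non-finite values")
        if self.family == "gaussian":
            self.y = self.y.astype(float)
            if not np.all(np.isfinite(self.y)):
                raise ValueError("response contains missing or non-finite values")
        elif self.family == "poisson":
            y_float = self.y.astype(float)
            if not np.all(np.isfinite(y_float)):
                raise ValueError("response contains missing or non-finite values")
            if np.any(y_float < 0) or np.any(y_float != np.round(y_float)):
                raise ValueError("poisson family requires nonnegative integer counts")
            self.y = y_float.astype(np.int64)
        else:
            raise ValueError(f"unknown family {self.family!r}")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class ChainState:
    """Current state (theta, gamma, beta[, z]) of the PARJ chain.

    ``beta`` is kept at full candidate length with exact zeros wherever the
    covariate is excluded; ``z`` is present only for the Poisson family.
    """

    theta: CovarianceParams
    model: ModelIndicator
    beta: np.ndarray
    z: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != self.model.gamma.shape:
            raise ValueError("beta must have one entry per candidate covariate")
        if np.any(self.beta[self.model.gamma == 0] != 0.0):
            raise ValueError("beta must be exactly zero for excluded covariates")
        if self.z is not None:
            self.z = np.asarray(self.z, dtype=float)

    def copy(self) -> "ChainState":
        return ChainState(
            self.theta,
            self.model.copy(),
            self.beta.copy(),
            None if self.z is None else self.z.copy(),
        )


@dataclass
class SamplerConfig:
    """Chain settings, proposal scales and prior hyperparameters.

    Defaults follow the package conventions: prior variance 10 on the log
    variance parameters, variance 1 on the log-range parameters (calibrated
    so most prior mass sits below the maximum observed distance), a
    triangular prior on the anisotropy correlation psi over (-1, 1) centred
    at 0, independent Bernoulli(1/2) model priors, and a diagonal normal
    coefficient prior with variance 100 on standardized covariates.
    Data-informed defaults (``None`` fields) are resolved at run time.
    """

    # chain
    n_iter: int = 20000
    burn_in: int = 5000
    seed: int = 0
    thin_z: int = 10
    store_z: bool = False
    # covariance structure
    correlation_family: str = "exponential"
    matern_smoothness: float = 1.5
    include_nugget: bool = True
    include_anisotropy: bool = True
    # proposal scales
    sd_log_variance: float = 0.3
    sd_log_range: float = 0.3
    psi_halfwidth: float = 0.2
    mala_step: Optional[float] = None  # None -> auto-tuned from 0.1
    auto_tune: bool = True
    # priors
    inclusion_prob: Union[float, Dict[str, float]] = 0.5
    forced: Tuple[str, ...] = ("intercept",)
    coef_prior_variance: float = 100.0
    intercept_prior_mean: Optional[float] = None
    log_variance_prior_mean: Optional[float] = None
    log_variance_prior_var: float = 10.0
    log_range_prior_mean: Optional[float] = None
    log_range_prior_var: float = 1.0
    # parameterization and switches
    variance_param: str = "independent"  # or "total_logit"
    sample_theta: bool = True
    prior_only: bool = False  # test harness: drop the data-likelihood term

    def validate(self, data: Optional[SpatialDataset] = None) -> List[str]:
        """Collect every configuration problem (empty list means valid)."""
        problems: List[str] = []
        if self.n_iter <= self.burn_in or self.burn_in < 0:
            problems.append(
                f"need n_iter > burn_in >= 0, got n_iter={self.n_iter}, "
                f"burn_in={self.burn_in}"
            )
        for name in ("sd_log_variance", "sd_log_range", "psi_halfwidth"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be > 0")
        if self.mala_step is not None and self.mala_step <= 0:
            problems.append("mala_step must be > 0 when given")
        if self.thin_z < 1:
            problems.append("thin_z must be >= 1")
        if self.correlation_family not in ("exponential", "spherical", "matern"):
            problems.append(f"unknown correlation_family {self.correlation_family!r}")
        if self.correlation_family == "matern" and self.matern_smoothness <= 0:
            problems.append("matern_smoothness must be > 0")
        if self.coef_prior_variance <= 0:
            problems.append("coef_prior_variance must be > 0")
        for name in ("log_variance_prior_var", "log_range_prior_var"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be > 0")
        if self.variance_param not in ("independent", "total_logit"):
            problems.append(f"unknown variance_param {self.variance_param!r}")
        if self.variance_param == "total_logit" and not self.include_nugget:
            problems.append("variance_param='total_logit' requires include_nugget")
        probs = (
            self.inclusion_prob.values()
            if isinstance(self.inclusion_prob, dict)
            else [self.inclusion_prob]
        )
        if any(not 0.0 <= float(v) <= 1.0 for v in probs):
            problems.append("inclusion probabilities must lie in [0, 1]")
        if data is not None:
            unknown = [name for name in self.forced if name not in data.covariate_names]
            if unknown:
                problems.append(f"forced covariates not in the dataset: {unknown}")
            if isinstance(self.inclusion_prob, dict):
                unknown = [
                    k for k in self.inclusion_prob if k not in data.covariate_names
                ]
                if unknown:
                    problems.append(f"inclusion_prob names not in the dataset: {unknown}")
        return problems

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "SamplerConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        d = dict(d)
        if "forced" in d and d["forced"] is not None:
            d["forced"] = tuple(d["forced"])
        return cls(**d)


# ---------------------------------------------------------------------------
# prior resolution
# ---------------------------------------------------------------------------


@dataclass
class _PriorSet:
    coef_prior: CoefficientPrior
    model_prior: ModelPrior
    forced_mask: np.ndarray
    lv_mean: float
    lv_var: float
    lr_mean: float
    lr_var: float


def _resolve_priors(data: SpatialDataset, config: SamplerConfig) -> _PriorSet:
    """Fill data-informed defaults and assemble prior objects."""
    forced_mask = np.array(
        [name in config.forced for name in data.covariate_names], dtype=bool
    )
    # model prior: Bernoulli inclusion probabilities, forced -> 1
    if isinstance(config.inclusion_prob, dict):
        pi = np.array(
            [float(config.inclusion_prob.get(n, 0.5)) for n in data.covariate_names]
        )
    else:
        pi = np.full(data.p, float(config.inclusion_prob))
    pi[forced_mask] = 1.0
    model_prior = ModelPrior(pi, forced_mask)

    # coefficient prior: constant (intercept-like) columns get a data-informed
    # mean, slopes get mean zero; diagonal covariance
    if config.intercept_prior_mean is not None:
        intercept_mean = float(config.intercept_prior_mean)
    elif data.family == "gaussian":
        intercept_mean = float(np.mean(data.y))
    else:
        intercept_mean = float(np.log(np.mean(data.y) + 0.1))
    mean = np.zeros(data.p)
    constant = np.ptp(data.X, axis=0) == 0.0
    mean[constant] = intercept_mean
    coef_prior = CoefficientPrior(mean, config.coef_prior_variance * np.eye(data.p))

    if config.log_variance_prior_mean is not None:
        lv_mean = float(config.log_variance_prior_mean)
    else:
        if data.family == "gaussian":
            resp_var = float(np.var(data.y))
        else:
            resp_var = float(np.var(np.log(data.y.astype(float) + 0.5)))
        lv_mean = float(np.log(max(resp_var, 1e-6) / 2.0))

    if config.log_range_prior_mean is not None:
        lr_mean = float(config.log_range_prior_mean)
    else:
        diff = data.coords[:, None, :] - data.coords[None, :, :]
        max_dist = float(np.sqrt((diff**2).sum(axis=-1)).max())
        lr_mean = float(np.log(max(max_dist, 1e-6) / 2.0))

    return _PriorSet(
        coef_prior,
        model_prior,
        forced_mask,
        lv_mean,
        float(config.log_variance_prior_var),
        lr_mean,
        float(config.log_range_prior_var),
    )


def _normal_logpdf(x: float, mean: float, var: float) -> float:
    return -0.5 * (_LOG_2PI + np.log(var) + (x - mean) ** 2 / var)


# ---------------------------------------------------------------------------
# the engine
# ---------------------------------------------------------------------------


class _Engine:
    """Mutable sampler state plus cached covariance factorization."""

    RW_TARGET = 0.35  # mid-point of the 0.2-0.5 random-walk acceptance band
    MALA_TARGET = 0.55  # mid-point of the 0.5-0.6 MALA acceptance band

    def __init__(
        self,
        data: SpatialDataset,
        config: SamplerConfig,
        rng: np.random.Generator,
        state: Optional[ChainState] = None,
    ) -> None:
        problems = config.validate(data)
        if problems:
            raise ValueError("invalid sampler configuration: " + "; ".join(problems))
        self.data = data
        self.config = config
        self.rng = rng
        self.priors = _resolve_priors(data, config)
        self.scales: Dict[str, float] = {
            "log_sill": config.sd_log_variance,
            "log_nugget": config.sd_log_variance,
            "log_range": config.sd_log_range,
            "psi": config.psi_halfwidth,
        }
        self.h = config.mala_step if config.mala_step is not None else 0.1
        self.tune_mala = config.mala_step is None or config.auto_tune
        # acceptance bookkeeping: {block: [accepts, proposals]}
        self.acc: Dict[str, List[int]] = {}
        self.window: Dict[str, List[int]] = {}
        if data.family == "poisson":
            self._log_yfact = float(np.sum(gammaln(data.y + 1.0)))
        self.state = state.copy() if state is not None else self._initial_state()
        self._check_state(self.state)
        self._set_theta(self.state.theta)

    # -- initialization ----------------------------------------------------

    def _initial_state(self) -> ChainState:
        cfg, pri, data = self.config, self.priors, self.data
        theta = CovarianceParams(
            log_sill=pri.lv_mean,
            log_ranges=(pri.lr_mean, pri.lr_mean),
            psi=0.0,
            log_nugget=pri.lv_mean if cfg.include_nugget else None,
            family=cfg.correlation_family,
            smoothness=(
                cfg.matern_smoothness if cfg.correlation_family == "matern" else None
            ),
        )
        gamma = np.ones(data.p, dtype=np.int8)
        # a covariate with prior inclusion probability 0 can never be in the model
        gamma[pri.model_prior.pi == 0.0] = 0
        gamma[pri.forced_mask] = 1
        model = ModelIndicator(gamma, pri.forced_mask)
        z = None
        if data.family == "poisson":
            z = np.log(data.y.astype(float) + 0.5)
        r = data.y.astype(float) if data.family == "gaussian" else z
        idx = model.included
        beta = np.zeros(data.p)
        if idx.size:
            beta[idx], *_ = np.linalg.lstsq(data.X[:, idx], r, rcond=None)
        return ChainState(theta, model, beta, z)

    def _check_state(self, state: ChainState) -> None:
        if (state.z is None) != (self.data.family == "gaussian"):
            raise ValueError("latent field z must be present iff family is poisson")
        if state.beta.shape != (self.data.p,):
            raise ValueError("state beta length does not match the candidate design")

    # -- cached covariance --------------------------------------------------

    def _try_factor(self, theta: CovarianceParams):
        try:
            sigma = build_covariance_matrix(self.data.coords, theta)
            L, _ = cholesky_with_jitter(sigma, context="spatial covariance")
            return sigma, L
        except (NumericalDegeneracyError, FloatingPointError):
            return None

    def _set_theta(self, theta: CovarianceParams) -> None:
        factored = self._try_factor(theta)
        if factored is None:
            raise NumericalDegeneracyError(
                f"initial spatial covariance is numerically degenerate at {theta}"
            )
        self.sigma, self.chol = factored
        self.state.theta = theta
        self._lcp_memo: Dict[bytes, float] = {}

    # -- log densities -------------------------------------------------------

    @property
    def response(self) -> np.ndarray:
        """Gaussian-layer response: y for gaussian family, current z otherwise."""
        if self.data.family == "gaussian":
            return self.data.y
        return self.state.z

    def _gauss_layer_ll(self, L: np.ndarray, beta: np.ndarray, r: np.ndarray) -> float:
        resid = r - self.data.X @ beta
        w = solve_triangular(L, resid, lower=True)
        log_det = 2.0 * float(np.sum(np.log(np.diag(L))))
        return -0.5 * (r.size * _LOG_2PI + log_det + float(w @ w))

    def _poisson_obs_ll(self, z: np.ndarray) -> float:
        if np.any(z > LATENT_EXP_GUARD):
            return -np.inf
        return float(self.data.y @ z - np.exp(z).sum()) - self._log_yfact

    def log_prior_theta(self, theta: CovarianceParams) -> float:
        pri, cfg = self.priors, self.config
        lp = _normal_logpdf(theta.log_sill, pri.lv_mean, pri.lv_var)
        if cfg.include_nugget:
            lp += _normal_logpdf(theta.log_nugget, pri.lv_mean, pri.lv_var)
        if cfg.include_anisotropy:
            lp += _normal_logpdf(theta.log_ranges[0], pri.lr_mean, pri.lr_var)
            lp += _normal_logpdf(theta.log_ranges[1], pri.lr_mean, pri.lr_var)
            lp += float(np.log1p(-abs(theta.psi)))  # triangular prior on (-1, 1)
        else:
            lp += _normal_logpdf(theta.log_ranges[0], pri.lr_mean, pri.lr_var)
        return lp

    def _theta_log_target(self, theta: CovarianceParams, L: np.ndarray) -> float:
        """Terms of the joint that move with theta (given beta, gamma, z)."""
        lp = self.log_prior_theta(theta)
        # for the poisson family the latent layer N(z; X beta, Sigma) is part
        # of the hierarchy, not the data likelihood, so it enters even when the
        # data-likelihood term is disabled
        if not self.config.prior_only or self.data.family == "poisson":
            lp += self._gauss_layer_ll(L, self.state.beta, self.response)
        return lp

    def log_joint(self, state: Optional[ChainState] = None) -> float:
        """Full log joint density of (theta, gamma, beta[, z]) and the data."""
        st = self.state if state is None else state
        factored = self._try_factor(st.theta)
        if factored is None:
            return -np.inf
        _, L = factored
        pri = self.priors
        lp = self.log_prior_theta(st.theta) + log_model_prior(st.model, pri.model_prior)
        idx = st.model.included
        if idx.size:
            sub = pri.coef_prior.restrict(st.model.gamma)
            Lv = np.linalg.cholesky(sub.covariance)
            w = solve_triangular(Lv, st.beta[idx] - sub.mean, lower=True)
            lp += -0.5 * (
                idx.size * _LOG_2PI
                + 2.0 * float(np.sum(np.log(np.diag(Lv))))
                + float(w @ w)
            )
        if self.data.family == "gaussian":
            if not self.config.prior_only:
                lp += self._gauss_layer_ll(L, st.beta, self.data.y)
        else:
            lp += self._gauss_layer_ll(L, st.beta, st.z)
            if not self.config.prior_only:
                lp += self._poisson_obs_ll(st.z)
        return lp

    # -- acceptance bookkeeping ----------------------------------------------

    def _record(self, block: str, accepted: bool) -> None:
        for registry in (self.acc, self.window):
            entry = registry.setdefault(block, [0, 0])
            entry[0] += int(accepted)
            entry[1] += 1

    def rates(self, registry: Optional[Dict[str, List[int]]] = None) -> Dict[str, float]:
        registry = self.acc if registry is None else registry
        return {k: (v[0] / v[1] if v[1] else float("nan")) for k, v in registry.items()}

    # -- step 1-4: spatial covariance parameters ------------------------------

    def _metropolis_theta(
        self, block: str, proposed: CovarianceParams, log_hastings: float = 0.0
    ) -> None:
        factored = self._try_factor(proposed)
        if factored is None:
            self._record(block, False)
            return
        sigma_p, L_p = factored
        log_ratio = (
            self._theta_log_target(proposed, L_p)
            - self._theta_log_target(self.state.theta, self.chol)
            + log_hastings
        )
        if np.log(self.rng.uniform()) < log_ratio:
            self.sigma, self.chol = sigma_p, L_p
            self.state.theta = proposed
            self._lcp_memo = {}
            self._record(block, True)
        else:
            self._record(block, False)

    def step_spatial(self) -> None:
        cfg = self.config
        theta = self.state.theta
        # variance parameters
        if cfg.variance_param == "total_logit" and cfg.include_nugget:
            # random walk on (log total variance, logit nugget proportion);
            # the Jacobian determinant of the map to (log sill, log nugget)
            # is exactly 1, so no acceptance correction is needed
            s2, t2 = np.exp(theta.log_sill), np.exp(theta.log_nugget)
            u = np.log(s2 + t2) + self.scales["log_sill"] * self.rng.standard_normal()
            v = np.log(t2 / s2) + self.scales["log_nugget"] * self.rng.standard_normal()
            prop_p = expit(v)
            total = np.exp(u)
            proposed = replace(
                theta,
                log_sill=float(np.log(total * (1.0 - prop_p))),
                log_nugget=float(np.log(total * prop_p)),
            )
            self._metropolis_theta("variance_total_logit", proposed)
        else:
            prop = theta.log_sill + self.scales["log_sill"] * self.rng.standard_normal()
            self._metropolis_theta("log_sill", replace(theta, log_sill=float(prop)))
            if cfg.include_nugget:
                theta = self.state.theta
                prop = (
                    theta.log_nugget
                    + self.scales["log_nugget"] * self.rng.standard_normal()
                )
                self._metropolis_theta(
                    "log_nugget", replace(theta, log_nugget=float(prop))
                )
        # range parameters
        theta = self.state.theta
        if cfg.include_anisotropy:
            for axis in (0, 1):
                theta = self.state.theta
                lr = list(theta.log_ranges)
                lr[axis] += self.scales["log_range"] * self.rng.standard_normal()
                self._metropolis_theta(
                    f"log_range{axis + 1}", replace(theta, log_ranges=tuple(lr))
                )
            # psi: uniform proposal on (psi - w, psi + w) truncated to (-1, 1);
            # the interval-length asymmetry enters the Hastings ratio
            theta = self.state.theta
            w = self.scales["psi"]
            lo, hi = max(-1.0, theta.psi - w), min(1.0, theta.psi + w)
            prop_psi = float(self.rng.uniform(lo, hi))
            len_fwd = hi - lo
            len_rev = min(1.0, prop_psi + w) - max(-1.0, prop_psi - w)
            self._metropolis_theta(
                "psi",
                replace(theta, psi=prop_psi),
                log_hastings=float(np.log(len_fwd) - np.log(len_rev)),
            )
        else:
            step = self.scales["log_range"] * self.rng.standard_normal()
            lr = theta.log_ranges[0] + step
            self._metropolis_theta(
                "log_range", replace(theta, log_ranges=(float(lr), float(lr)))
            )

    # -- step 5: partial-analytic model move ----------------------------------

    def _lcp(self, model: ModelIndicator) -> float:
        key = model.gamma.tobytes()
        if key not in self._lcp_memo:
            self._lcp_memo[key] = log_conditional_model_posterior(
                self.response,
                self.data.X,
                model,
                self.sigma,
                self.priors.coef_prior,
                self.priors.model_prior,
            )
        return self._lcp_memo[key]

    def step_model(self) -> None:
        if self.state.model.selectable.size == 0:
            return
        proposed, log_qr = propose_model_move(self.state.model, self.rng)
        log_ratio = self._lcp(proposed) - self._lcp(self.state.model) + log_qr
        if np.log(self.rng.uniform()) < log_ratio:
            self.state.model = proposed
            # partial-analytic draw: refresh beta under the accepted model
            self.step_beta()
            self._record("model", True)
        else:
            self._record("model", False)

    # -- step 6: Gibbs coefficient draw ---------------------------------------

    def step_beta(self) -> None:
        idx = self.state.model.included
        beta = np.zeros(self.data.p)
        if idx.size:
            sub = self.priors.coef_prior.restrict(self.state.model.gamma)
            fc = beta_full_conditional(
                self.response, self.data.X[:, idx], self.sigma, sub
            )
            beta[idx] = draw_beta(fc, self.rng)
        self.state.beta = beta

    # -- step 7: Langevin-Hastings latent-field update --------------------------

    def latent_gradient(self, z: np.ndarray) -> np.ndarray:
        """grad_z log joint = (y - exp(z)) - Sigma^-1 (z - X beta)."""
        mean = self.data.X @ self.state.beta
        prior_part = cho_solve((self.chol, True), z - mean)
        with np.errstate(over="ignore"):
            rate = np.exp(np.minimum(z, LATENT_EXP_GUARD))
        return (self.data.y - rate) - prior_part

    def _latent_log_target(self, z: np.ndarray) -> float:
        ll = self._poisson_obs_ll(z) if not self.config.prior_only else 0.0
        if not np.isfinite(ll):
            return -np.inf
        return ll + self._gauss_layer_ll(self.chol, self.state.beta, z)

    def step_latent(self, gradient_fn: Optional[Callable] = None) -> None:
        if self.data.family != "poisson":
            raise ValueError("latent-field updates only apply to the poisson family")
        grad = gradient_fn if gradient_fn is not None else self.latent_gradient
        z = self.state.z
        h = self.h
        mean_fwd = z + 0.5 * h * grad(z)
        z_prop = mean_fwd + np.sqrt(h) * self.rng.standard_normal(z.size)
        mean_rev = z_prop + 0.5 * h * grad(z_prop)
        log_q_fwd = -float(np.sum((z_prop - mean_fwd) ** 2)) / (2.0 * h)
        log_q_rev = -float(np.sum((z - mean_rev) ** 2)) / (2.0 * h)
        log_ratio = (
            self._latent_log_target(z_prop)
            - self._latent_log_target(z)
            + log_q_rev
            - log_q_fwd
        )
        if np.log(self.rng.uniform()) < log_ratio:
            self.state.z = z_prop
            self._lcp_memo = {}
            self._record("mala", True)
        else:
            self._record("mala", False)

    # -- burn-in adaptation ------------------------------------------------------

    _BLOCK_SCALE = {
        "log_sill": "log_sill",
        "log_nugget": "log_nugget",
        "variance_total_logit": "log_sill",
        "log_range": "log_range",
        "log_range1": "log_range",
        "log_range2": "log_range",
        "psi": "psi",
    }

    def adapt(self) -> None:
        """Robbins-Monro-style scale adjustment from the current window."""
        rates = self.rates(self.window)
        for block, rate in rates.items():
            if not np.isfinite(rate):
                continue
            if block == "mala":
                if self.tune_mala:
                    self.h = float(
                        np.clip(self.h * np.exp(rate - self.MALA_TARGET), 1e-8, 1e3)
                    )
            elif block == "model":
                continue
            else:
                key = self._BLOCK_SCALE[block]
                new = self.scales[key] * np.exp(rate - self.RW_TARGET)
                cap = 2.0 if key == "psi" else 1e3
                self.scales[key] = float(np.clip(new, 1e-3, cap))
        self.window = {}


# ---------------------------------------------------------------------------
# public single-step wrappers (used heavily by the tests)
# ---------------------------------------------------------------------------


def log_joint(state: ChainState, data: SpatialDataset, config: SamplerConfig) -> float:
    """Log joint density of the state and data under the configured priors."""
    return _Engine(data, config, np.random.default_rng(0), state).log_joint()


def update_spatial_params(
    state: ChainState,
    data: SpatialDataset,
    config: SamplerConfig,
    rng: np.random.Generator,
) -> ChainState:
    """One sweep of Metropolis updates over the spatial covariance parameters."""
    eng = _Engine(data, config, rng, state)
    eng.step_spatial()
    return eng.state


def parj_model_update(
    state: ChainState,
    data: SpatialDataset,
    config: SamplerConfig,
    rng: np.random.Generator,
) -> ChainState:
    """One partial-analytic reversible-jump model move (with beta refresh)."""
    eng = _Engine(data, config, rng, state)
    eng.step_model()
    return eng.state


def latent_log_gradient(state: ChainState, data: SpatialDataset) -> np.ndarray:
    """Gradient of the log joint with respect to the latent field z."""
    if data.family != "poisson":
        raise ValueError("the latent-field gradient only applies to the poisson family")
    cfg = SamplerConfig(
        forced=(),
        include_nugget=state.theta.log_nugget is not None,
        correlation_family=state.theta.family,
        matern_smoothness=state.theta.smoothness or 1.5,
    )
    eng = _Engine(data, cfg, np.random.default_rng(0), state)
    return eng.latent_gradient(state.z)


def mala_update_latent(
    state: ChainState,
    data: SpatialDataset,
    config: SamplerConfig,
    rng: np.random.Generator,
    _gradient_fn: Optional[Callable] = None,
) -> ChainState:
    """One whole-vector Langevin-Hastings update of the latent field."""
    eng = _Engine(data, config, rng, state)
    eng.step_latent(gradient_fn=_gradient_fn)
    return eng.state


# ---------------------------------------------------------------------------
# the full chain
# ---------------------------------------------------------------------------


def run_parj(
    data: SpatialDataset,
    config: SamplerConfig,
    initial_state: Optional[ChainState] = None,
) -> ChainOutput:
    """Run the full PARJ chain and return post-burn-in draws.

    Per iteration: spatial-parameter Metropolis sweeps (unless
    ``config.sample_theta`` is off), the partial-analytic model move, a Gibbs
    coefficient draw, and — for the Poisson family — a MALA latent-field
    update.  Fixed ``config.seed`` gives bit-identical output.
    """
    problems = config.validate(data)
    if problems:
        raise ValueError("invalid sampler configuration: " + "; ".join(problems))
    rng = np.random.default_rng(config.seed)
    eng = _Engine(data, config, rng, initial_state)

    n_keep = config.n_iter - config.burn_in
    theta_cols = ["log_sill"]
    if config.include_nugget:
        theta_cols.append("log_nugget")
    theta_cols += ["log_range1", "log_range2"]
    if config.include_anisotropy:
        theta_cols.append("psi")
    theta_store = np.empty((n_keep, len(theta_cols)))
    gamma_store = np.empty((n_keep, data.p), dtype=np.int8)
    beta_store = np.empty((n_keep, data.p))
    store_z = config.store_z and data.family == "poisson"
    z_store = [] if store_z else None

    acceptance_log: Dict[str, list] = {}
    block_marks: Dict[str, List[int]] = {}
    burn_marks: Dict[str, Tuple[int, int]] = {}

    for it in range(config.n_iter):
        if config.sample_theta:
            eng.step_spatial()
        eng.step_model()
        eng.step_beta()
        if data.family == "poisson":
            eng.step_latent()
        if config.auto_tune and it < config.burn_in and (it + 1) % 100 == 0:
            eng.adapt()
        if it + 1 == config.burn_in:
            burn_marks = {k: (v[0], v[1]) for k, v in eng.acc.items()}
        if it >= config.burn_in:
            k = it - config.burn_in
            st = eng.state
            row = [st.theta.log_sill]
            if config.include_nugget:
                row.append(st.theta.log_nugget)
            row += [st.theta.log_ranges[0], st.theta.log_ranges[1]]
            if config.include_anisotropy:
                row.append(st.theta.psi)
            theta_store[k] = row
            gamma_store[k] = st.model.gamma
            beta_store[k] = st.beta
            if store_z and k % config.thin_z == 0:
                z_store.append(st.z.copy())
        if (it + 1) % 1000 == 0:
            for block, (a, m) in eng.acc.items():
                prev_a, prev_m = block_marks.get(block, (0, 0))
                acceptance_log.setdefault(block, []).append(
                    (a - prev_a) / max(m - prev_m, 1)
                )
                block_marks[block] = (a, m)
            logger.info(
                "iteration %d: acceptance %s | model %s",
                it + 1,
                {k: round(v[-1], 3) for k, v in acceptance_log.items()},
                eng.state.model.key(),
            )

    # post-burn-in acceptance rates (the adaptation phase is excluded)
    post = {}
    for block, (a, m) in eng.acc.items():
        a0, m0 = burn_marks.get(block, (0, 0))
        post[block] = (a - a0) / max(m - m0, 1)
    acceptance_log["_overall"] = [post]
    acceptance_log["_mala_step"] = [eng.h]
    return ChainOutput(
        theta_draws=pd.DataFrame(theta_store, columns=theta_cols),
        gamma_draws=gamma_store,
        beta_draws=beta_store,
        covariate_names=list(data.covariate_names),
        forced_mask=eng.priors.forced_mask,
        config_snapshot=config.to_dict(),
        acceptance_log=acceptance_log,
        z_draws=np.asarray(z_store) if store_z and z_store else None,
    )
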