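"""Posterior summaries: model probabilities, inclusion probabilities, mixtures.

Sample averages over the reversible-jump chain approximate the posterior
quantities of interest: the posterior model probability (PMP) of each visited
model is its visit fraction, the posterior inclusion probability (PIP) of a
covariate is the fraction of draws that include it, and the model-averaged
posterior of a coefficient is a two-part mixture — a point mass at zero of
size 1 - PIP plus the conditional distribution of the coefficient given
inclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "ChainOutput",
    "PosteriorSummary",
    "RatioPosterior",
    "compute_pmp",
    "compute_pip",
    "coefficient_posterior_mixture",
    "hpd_interval",
    "coefficient_ratio_posterior",
    "summarize_chain",
    "plot_coefficient_posteriors",
]


@dataclass
class ChainOutput:
    """Stored post-burn-in draws of a reversible-jump run.

    ``theta_draws`` is a DataFrame (one row per stored iteration, spatial
    parameters on sampling scale); ``gamma_draws`` is an m x p 0/1 matrix;
    ``beta_draws`` is m x p with zeros wherever the covariate is excluded;
    ``z_draws`` holds thinned latent-field draws for the Poisson family.
    """

    theta_draws: pd.DataFrame
    gamma_draws: np.ndarray
    beta_draws: np.ndarray
    covariate_names: List[str]
    forced_mask: np.ndarray
    config_snapshot: dict
    acceptance_log: Dict[str, list] = field(default_factory=dict)
    z_draws: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.gamma_draws = np.asarray(self.gamma_draws, dtype=np.int8)
        self.beta_draws = np.asarray(self.beta_draws, dtype=float)
        self.forced_mask = np.asarray(self.forced_mask, dtype=bool)
        m, p = self.gamma_draws.shape
        if self.beta_draws.shape != (m, p):
            raise ValueError("beta draws must match gamma draws in shape")
        if len(self.covariate_names) != p:
            raise ValueError("covariate_names length must equal p")
        if np.any(self.gamma_draws[:, self.forced_mask] != 1):
            raise ValueError("stored draws violate the forced-covariate mask")

    @property
    def n_draws(self) -> int:
        return self.gamma_draws.shape[0]

    @property
    def p(self) -> int:
        return self.gamma_draws.shape[1]

    def _index_of(self, j: Union[int, str]) -> int:
        if isinstance(j, str):
            return self.covariate_names.index(j)
        return int(j)


def compute_pmp(chain: ChainOutput) -> pd.DataFrame:
    """Posterior model probabilities = visit fractions of each visited model.

    Returns a DataFrame indexed by the model's inclusion bit-string, sorted
    by descending probability, with columns ``count`` and ``pmp``; the number
    of distinct visited models is ``len(result)``.
    """
    if chain.n_draws == 0:
        raise ValueError("cannot summarize an empty chain")
    keys = ["".join(map(str, row)) for row in chain.gamma_draws]
    counts = pd.Series(keys, name="model").value_counts()
    table = pd.DataFrame({"count": counts, "pmp": counts / chain.n_draws})
    table.index.name = "model"
    table.attrs["n_visited"] = len(table)
    return table


def compute_pip(chain: ChainOutput) -> pd.Series:
    """Posterior inclusion probability per covariate (fraction of draws).

    By construction pip_j equals the sum of PMPs over models containing j.
    """
    if chain.n_draws == 0:
        raise ValueError("cannot summarize an empty chain")
    pip = chain.gamma_draws.mean(axis=0)
    return pd.Series(pip, index=chain.covariate_names, name="pip")


def coefficient_posterior_mixture(
    chain: ChainOutput, j: Union[int, str]
) -> Tuple[float, np.ndarray]:
    """Spike-and-slab mixture for coefficient j.

    Returns ``(mass_at_zero, conditional_draws)`` where ``mass_at_zero`` is
    1 - PIP_j and ``conditional_draws`` are the beta_j draws from iterations
    that include covariate j (possibly empty).
    """
    idx = chain._index_of(j)
    included = chain.gamma_draws[:, idx] == 1
    mass_at_zero = 1.0 - float(included.mean()) if chain.n_draws else 1.0
    return mass_at_zero, chain.beta_draws[included, idx]


def hpd_interval(draws: np.ndarray, level: float = 0.95) -> Tuple[float, float]:
    """Shortest contiguous interval containing ``level`` posterior mass.

    Scans the sorted sample for the narrowest window holding
    ``ceil(level * m)`` draws (the standard empirical HPD estimator for a
    unimodal posterior).
    """
    draws = np.sort(np.asarray(draws, dtype=float).ravel())
    m = draws.size
    if m < 50:
        raise ValueError(f"need at least 50 draws for an HPD interval, got {m}")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    k = int(np.ceil(level * m))
    widths = draws[k - 1 :] - draws[: m - k + 1]
    i = int(np.argmin(widths))
    return float(draws[i]), float(draws[i + k - 1])


@dataclass
class RatioPosterior:
    """Model-averaged posterior of |beta_denominator| / |beta_numerator|.

    ``p_numerator_larger`` is the posterior probability that the numerator
    covariate has the larger absolute coefficient; both quantities condition
    on draws where the two covariates are jointly included (``n_both``
    reports how many such draws exist; ``empty`` flags none).
    """

    numerator: str
    denominator: str
    p_numerator_larger: float
    ratio_draws: np.ndarray
    n_both: int

    @property
    def empty(self) -> bool:
        return self.n_both == 0


def coefficient_ratio_posterior(
    chain: ChainOutput, j: Union[int, str], k: Union[int, str]
) -> RatioPosterior:
    """Posterior of the coefficient-magnitude comparison between j and k.

    Conditions on iterations where both covariates are included; ratios are
    reported as |beta_k| / |beta_j| (denominator over numerator).
    """
    idx_j, idx_k = chain._index_of(j), chain._index_of(k)
    if idx_j == idx_k:
        raise ValueError("ratio requires two distinct covariates")
    both = (chain.gamma_draws[:, idx_j] == 1) & (chain.gamma_draws[:, idx_k] == 1)
    n_both = int(both.sum())
    name_j, name_k = chain.covariate_names[idx_j], chain.covariate_names[idx_k]
    if n_both == 0:
        return RatioPosterior(name_j, name_k, float("nan"), np.empty(0), 0)
    bj = np.abs(chain.beta_draws[both, idx_j])
    bk = np.abs(chain.beta_draws[both, idx_k])
    p_larger = float(np.mean(bj > bk))
    with np.errstate(divide="ignore"):
        ratios = bk / bj
    return RatioPosterior(name_j, name_k, p_larger, ratios, n_both)


@dataclass
class PosteriorSummary:
    """Bundle of the standard posterior summaries of one chain."""

    pmp_table: pd.DataFrame
    pip: pd.Series
    coefficient_means: pd.Series
    n_visited_models: int


def summarize_chain(chain: ChainOutput) -> PosteriorSummary:
    """PMP table, PIP vector and model-averaged coefficient means."""
    pmp = compute_pmp(chain)
    pip = compute_pip(chain)
    coef_means = pd.Series(
        chain.beta_draws.mean(axis=0), index=chain.covariate_names, name="posterior_mean"
    )
    return PosteriorSummary(pmp, pip, coef_means, int(pmp.attrs["n_visited"]))


def plot_coefficient_posteriors(chain: ChainOutput, names=None, level: float = 0.95):
    """Spike-plus-density panels: P(beta_j = 0 | y) bar plus a kernel estimate.

    Presentation-layer convenience; requires matplotlib.  The kernel estimate
    (Gaussian, Silverman bandwidth) is fit to the conditional draws only.
    """
    import matplotlib.pyplot as plt
    from scipy.stats import gaussian_kde

    if names is None:
        pip = compute_pip(chain)
        sel = pip[~pd.Series(chain.forced_mask, index=pip.index)]
        names = list(sel.sort_values(ascending=False).index[:4])
    fig, axes = plt.subplots(1, len(names), figsize=(3.2 * len(names), 3.0))
    axes = np.atleast_1d(axes)
    for ax, name in zip(axes, names):
        mass0, draws = coefficient_posterior_mixture(chain, name)
        ax.bar([0.0], [mass0], width=0.04, color="0.3", zorder=3)
        if draws.size >= 2 and np.std(draws) > 0:
            kde = gaussian_kde(draws)
            grid = np.linspace(draws.min(), draws.max(), 256)
            ax.plot(grid, (1.0 - mass0) * kde(grid), color="C0")
        ax.set_title(name)
        ax.set_xlabel("coefficient")
    fig.tight_layout()
    return fig
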