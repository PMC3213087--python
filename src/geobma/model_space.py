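"""Candidate-model space: inclusion indicators, Bernoulli model prior, moves.

A model M_k is identified by a binary inclusion vector gamma over the p
candidate covariates.  Covariates flagged as *forced* (typically the
intercept) are in every model and excluded from the 2^p_selectable count.
The model prior treats inclusion of each selectable covariate as an
independent Bernoulli trial with probability pi_j, which admits both the
uniform prior (pi_j = 1/2) and informative a-priori weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import List, Tuple, Union

import numpy as np

__all__ = [
    "ModelIndicator",
    "ModelPrior",
    "log_model_prior",
    "enumerate_model_space",
    "propose_model_move",
    "MAX_ENUMERABLE",
]

#: Largest selectable-covariate count for exhaustive enumeration (2^20 models).
MAX_ENUMERABLE = 20


@dataclass
class ModelIndicator:
    """Binary inclusion vector gamma plus the mask of forced covariates."""

    gamma: np.ndarray
    forced_mask: np.ndarray

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=np.int8)
        self.forced_mask = np.asarray(self.forced_mask, dtype=bool)
        if self.gamma.ndim != 1 or self.gamma.shape != self.forced_mask.shape:
            raise ValueError("gamma and forced_mask must be 1-d with equal length")
        if self.gamma.size < 1:
            raise ValueError("a model needs at least one candidate covariate")
        if not np.all(np.isin(self.gamma, (0, 1))):
            raise ValueError("gamma entries must be 0 or 1")
        if np.any(self.gamma[self.forced_mask] != 1):
            raise ValueError("forced covariates must have gamma = 1")

    @property
    def p(self) -> int:
        return self.gamma.size

    @property
    def selectable(self) -> np.ndarray:
        """Indices of covariates subject to selection."""
        return np.flatnonzero(~self.forced_mask)

    @property
    def included(self) -> np.ndarray:
        return np.flatnonzero(self.gamma == 1)

    def key(self) -> str:
        """Bit-string over all p candidates, e.g. '1101'."""
        return "".join("1" if g else "0" for g in self.gamma)

    def copy(self) -> "ModelIndicator":
        return ModelIndicator(self.gamma.copy(), self.forced_mask.copy())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ModelIndicator)
            and np.array_equal(self.gamma, other.gamma)
            and np.array_equal(self.forced_mask, other.forced_mask)
        )

    def __hash__(self) -> int:
        return hash((self.gamma.tobytes(), self.forced_mask.tobytes()))


@dataclass
class ModelPrior:
    """Independent-Bernoulli prior inclusion probabilities pi_j."""

    pi: np.ndarray
    forced_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.forced_mask is None:
            self.forced_mask = np.zeros(self.pi.shape, dtype=bool)
        self.forced_mask = np.asarray(self.forced_mask, dtype=bool)
        if self.pi.ndim != 1 or self.pi.shape != self.forced_mask.shape:
            raise ValueError("pi and forced_mask must be 1-d with equal length")
        if np.any(self.pi < 0) or np.any(self.pi > 1):
            raise ValueError("prior inclusion probabilities must lie in [0, 1]")
        if np.any(self.pi[self.forced_mask] != 1.0):
            raise ValueError("forced covariates require prior inclusion probability 1")


def log_model_prior(model: ModelIndicator, prior: ModelPrior) -> float:
    """Log of the Bernoulli-product model prior.

    Sums ``gamma_j log pi_j + (1 - gamma_j) log(1 - pi_j)`` over selectable
    covariates; pi_j in {0, 1} is handled exactly (the result is -inf only
    when the indicator disagrees with a degenerate prior).
    """
    if prior.pi.shape != model.gamma.shape:
        raise ValueError(
            f"model has {model.p} candidates but prior has {prior.pi.size} entries"
        )
    sel = ~model.forced_mask
    g = model.gamma[sel].astype(float)
    pi = prior.pi[sel]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(g == 1.0, np.log(pi), np.log1p(-pi))
    # 0 * log 0 situations cannot arise: each term picks exactly one branch
    return float(np.sum(terms))


def enumerate_model_space(
    p_selectable: int, forced_mask: Union[np.ndarray, None] = None
) -> List[ModelIndicator]:
    """All 2^p_selectable models; forced covariates included in every one.

    ``forced_mask`` (length p over all candidates) defaults to no forced
    covariates, in which case p = p_selectable.  Refuses p_selectable > 20.
    """
    if p_selectable < 0:
        raise ValueError("p_selectable must be nonnegative")
    if p_selectable > MAX_ENUMERABLE:
        raise ValueError(
            f"p_selectable={p_selectable} would enumerate 2^{p_selectable} models; "
            "use the reversible-jump sampler instead of exhaustive enumeration"
        )
    if forced_mask is None:
        forced_mask = np.zeros(p_selectable, dtype=bool)
    forced_mask = np.asarray(forced_mask, dtype=bool)
    sel_idx = np.flatnonzero(~forced_mask)
    if sel_idx.size != p_selectable:
        raise ValueError(
            f"forced_mask leaves {sel_idx.size} selectable covariates, "
            f"expected {p_selectable}"
        )
    models = []
    for bits in product((0, 1), repeat=p_selectable):
        gamma = np.ones(forced_mask.size, dtype=np.int8)
        gamma[sel_idx] = bits
        models.append(ModelIndicator(gamma, forced_mask))
    return models


def propose_model_move(
    model: ModelIndicator, rng: np.random.Generator
) -> Tuple[ModelIndicator, float]:
    """Discrete random-walk model proposal: toggle one selectable covariate.

    The covariate is chosen uniformly over the selectable set; if it is in
    the model it is removed, otherwise added.  The toggle is symmetric, so
    the log proposal ratio is exactly 0.
    """
    sel = model.selectable
    if sel.size == 0:
        raise ValueError("no selectable covariates to propose a move for")
    j = int(sel[rng.integers(sel.size)])
    proposed = model.copy()
    proposed.gamma[j] = 1 - proposed.gamma[j]
    return proposed, 0.0
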