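"""Anisotropic spatial covariance functions.

The spatial error process is a stationary Gaussian field with covariance

    Cov(s_i, s_j) = sigma^2 * rho(||s_i - s_j||_A) + tau^2 * 1{i = j},

where ``sigma^2`` is the partial sill, ``tau^2`` the nugget, ``rho`` an
isotropic correlation function (exponential, spherical or Matern), and
``||h||_A = sqrt(h' A h)`` a Mahalanobis-type distance through a positive
definite 2x2 anisotropy matrix A.

A is factored as ``A = D R D`` with ``D = diag(1/d1, 1/d2)`` holding inverse
per-axis ranges and ``R = [[1, psi], [psi, 1]]`` a correlation matrix whose
single free entry ``psi`` in (-1, 1) encodes the anisotropy angle.  With this
convention the isotropic limit (equal ranges, psi = 0) recovers the textbook
exponential model ``exp(-h / d)``, and any psi in (-1, 1) gives a valid A, so
the sampler can move over anisotropy parameters without boundary constraints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.special import gammaln, kv

__all__ = [
    "CovarianceParams",
    "NumericalDegeneracyError",
    "build_anisotropy_matrix",
    "effective_distance",
    "effective_distance_matrix",
    "correlation_value",
    "build_covariance_matrix",
    "cholesky_with_jitter",
]

CORRELATION_FAMILIES = ("exponential", "spherical", "matern")
DEFAULT_MATERN_SMOOTHNESS = 1.5

#: Relative diagonal jitter applied once if the first Cholesky attempt fails.
JITTER_FRACTION = 1e-10


class NumericalDegeneracyError(RuntimeError):
    """A covariance matrix stayed non positive definite after the jitter rescue."""


@dataclass(frozen=True)
class CovarianceParams:
    """Parameters of the spatial covariance, on sampling (log / raw) scale.

    Parameters
    ----------
    log_sill
        Log of the partial-sill variance sigma^2.
    log_ranges
        Logs of the per-axis range scales (d1, d2), in coordinate distance
        units.  Equal entries plus ``psi = 0`` give an isotropic model.
    psi
        Off-diagonal of the 2x2 anisotropy correlation factor R; must lie
        strictly inside (-1, 1).
    log_nugget
        Log of the nugget variance tau^2, or ``None`` when the model carries
        no nugget.
    family
        Correlation family: ``exponential``, ``spherical`` or ``matern``.
    smoothness
        Matern smoothness nu (> 0); only allowed (and required) for the
        Matern family.  Fixed by configuration, never sampled.
    """

    log_sill: float
    log_ranges: Tuple[float, float]
    psi: float = 0.0
    log_nugget: Optional[float] = None
    family: str = "exponential"
    smoothness: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family not in CORRELATION_FAMILIES:
            raise ValueError(
                f"unknown correlation family {self.family!r}; "
                f"expected one of {CORRELATION_FAMILIES}"
            )
        if len(self.log_ranges) != 2:
            raise ValueError("log_ranges must hold exactly two per-axis values")
        if not np.all(np.isfinite(self.log_ranges)) or not np.isfinite(self.log_sill):
            raise ValueError("covariance parameters must be finite")
        if not abs(self.psi) < 1.0:
            raise ValueError(f"psi must lie strictly in (-1, 1), got {self.psi}")
        if self.family == "matern":
            if self.smoothness is None or self.smoothness <= 0:
                raise ValueError("matern family requires smoothness > 0")
        elif self.smoothness is not None:
            raise ValueError("smoothness is only meaningful for the matern family")

    @property
    def sill(self) -> float:
        return float(np.exp(self.log_sill))

    @property
    def nugget(self) -> float:
        return 0.0 if self.log_nugget is None else float(np.exp(self.log_nugget))

    @property
    def ranges(self) -> np.ndarray:
        return np.exp(np.asarray(self.log_ranges, dtype=float))


def build_anisotropy_matrix(log_ranges, psi: float) -> np.ndarray:
    """Assemble A = D R D from per-axis log ranges and the correlation psi.

    D holds inverse ranges, so larger ranges yield slower correlation decay.
    ``det(A) = (1 - psi^2) / (d1^2 d2^2) > 0`` for every valid input.
    """
    if not abs(psi) < 1.0:
        raise ValueError(f"invalid anisotropy correlation psi={psi}; |psi| must be < 1")
    inv_ranges = np.exp(-np.asarray(log_ranges, dtype=float))
    if inv_ranges.shape != (2,):
        raise ValueError("log_ranges must hold exactly two per-axis values")
    d = np.diag(inv_ranges)
    r = np.array([[1.0, psi], [psi, 1.0]])
    return d @ r @ d


def effective_distance(s_i, s_j, A: np.ndarray) -> float:
    """Mahalanobis-type distance sqrt((s_i - s_j)' A (s_i - s_j))."""
    h = np.asarray(s_i, dtype=float) - np.asarray(s_j, dtype=float)
    q = float(h @ A @ h)
    # guard tiny negative round-off for coincident sites
    return float(np.sqrt(max(q, 0.0)))


def effective_distance_matrix(coords: np.ndarray, A: np.ndarray) -> np.ndarray:
    """All pairwise effective distances for an n x 2 coordinate array."""
    coords = np.asarray(coords, dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    q = np.einsum("ijk,kl,ijl->ij", diff, A, diff)
    return np.sqrt(np.clip(q, 0.0, None))


def correlation_value(d, family: str = "exponential", smoothness: Optional[float] = None):
    """Isotropic correlation rho(d) on the effective-distance scale.

    The range is already absorbed into the anisotropy matrix, so the
    exponential family is ``exp(-d)``, the spherical family has support
    ``d < 1``, and the Matern family is evaluated at the raw effective
    distance.  Accepts scalars or arrays; rho(0) = 1 in every family.
    """
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValueError("distances must be nonnegative")
    if family == "exponential":
        out = np.exp(-d_arr)
    elif family == "spherical":
        inside = np.clip(d_arr, 0.0, 1.0)
        out = np.where(d_arr < 1.0, 1.0 - 1.5 * inside + 0.5 * inside**3, 0.0)
    elif family == "matern":
        nu = DEFAULT_MATERN_SMOOTHNESS if smoothness is None else float(smoothness)
        if nu <= 0:
            raise ValueError("matern smoothness must be > 0")
        with np.errstate(invalid="ignore"):
            safe = np.where(d_arr > 0, d_arr, 1.0)
            log_rho = (
                (1.0 - nu) * np.log(2.0)
                - gammaln(nu)
                + nu * np.log(safe)
                + np.log(kv(nu, safe))
            )
            out = np.where(d_arr > 0, np.exp(log_rho), 1.0)
    else:
        raise ValueError(f"unknown correlation family {family!r}")
    if np.isscalar(d) or np.ndim(d) == 0:
        return float(out)
    return out


def build_covariance_matrix(coords: np.ndarray, params: CovarianceParams) -> np.ndarray:
    """Dense n x n spatial covariance Sigma(theta).

    ``Sigma_ij = sigma^2 rho(||s_i - s_j||_A) + tau^2 1{i=j}``; the diagonal
    is exactly ``sigma^2 + tau^2``.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[0] < 1 or coords.shape[1] != 2:
        raise ValueError("coords must be an n x 2 array with n >= 1")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    A = build_anisotropy_matrix(params.log_ranges, params.psi)
    dist = effective_distance_matrix(coords, A)
    sigma = params.sill * correlation_value(dist, params.family, params.smoothness)
    sigma[np.diag_indices_from(sigma)] += params.nugget
    return sigma


def cholesky_with_jitter(
    sigma: np.ndarray, context: str = "covariance matrix"
) -> Tuple[np.ndarray, bool]:
    """Lower Cholesky factor with a single bounded jitter rescue.

    If the first factorization fails, ``JITTER_FRACTION * mean(diag)`` is
    added to the diagonal once and the factorization retried; a second
    failure raises :class:`NumericalDegeneracyError` naming the context.

    Returns ``(L, used_jitter)`` so callers can flag degenerate inputs.
    """
    try:
        return np.linalg.cholesky(sigma), False
    except np.linalg.LinAlgError:
        pass
    scale = float(np.mean(np.diag(sigma)))
    jittered = sigma + JITTER_FRACTION * scale * np.eye(sigma.shape[0])
    try:
        return np.linalg.cholesky(jittered), True
    except np.linalg.LinAlgError:
        raise NumericalDegeneracyError(
            f"{context} is not positive definite even after adding diagonal "
            f"jitter {JITTER_FRACTION * scale:.3e}; diagonal scale {scale:.6g}"
        ) from None
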