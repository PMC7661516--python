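"""Matérn spatial covariance and Gaussian-process helpers.

The spatially structured residual of the hurdle model is a stationary
Gaussian random field on planar site coordinates (km) with a Matérn
covariance of smoothness ``nu = 1``:

    C(d) = sigma^2 * (kappa d) K_1(kappa d),      kappa = sqrt(8) / range

where ``K_1`` is the modified Bessel function of the second kind.  The
``range`` parameter is the *practical range*: the distance at which the
correlation has fallen to roughly 0.14, the convention used by SPDE-based
geostatistics.  Coordinates are planar km with Euclidean distances; the
study extent (a few hundred km) tolerates a local projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from scipy.spatial.distance import cdist
from scipy.special import k1

#: Matérn smoothness is fixed; only variance and range are estimated.
MATERN_NU = 1.0


@dataclass(frozen=True)
class SpatialFieldParams:
    """Marginal standard deviation and practical range (km) of the field."""

    marginal_sd: float
    range_km: float
    nu: float = MATERN_NU

    def __post_init__(self):
        if self.marginal_sd <= 0:
            raise ValueError("marginal_sd must be > 0")
        if self.range_km <= 0:
            raise ValueError("range_km must be > 0")


def matern_cov(dist_km, params: SpatialFieldParams) -> np.ndarray:
    """Matérn(nu=1) covariance at the given distances (km).

    Returns ``sigma^2`` at distance 0 and decays strictly monotonically;
    vectorised over ``dist_km``.
    """
    d = np.asarray(dist_km, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be >= 0")
    kappa = np.sqrt(8.0 * params.nu) / params.range_km
    x = kappa * d
    with np.errstate(invalid="ignore"):
        corr = np.where(x > 0, x * k1(np.where(x > 0, x, 1.0)), 1.0)
    return params.marginal_sd ** 2 * corr


def cov_matrix(coords_km: np.ndarray, params: SpatialFieldParams,
               jitter: float = 1e-8) -> np.ndarray:
    """Dense covariance matrix over site coordinates, with a stabilising jitter."""
    d = cdist(coords_km, coords_km)
    c = matern_cov(d, params)
    return c + jitter * params.marginal_sd ** 2 * np.eye(len(coords_km))


def chol_cov(coords_km: np.ndarray, params: SpatialFieldParams) -> np.ndarray:
    return np.linalg.cholesky(cov_matrix(coords_km, params))


def gaussian_logpdf(w: np.ndarray, chol: np.ndarray) -> float:
    """log N(w; 0, L L') from the Cholesky factor."""
    z = solve_triangular(chol, w, lower=True)
    logdet = np.sum(np.log(np.diag(chol)))
    return float(-0.5 * z @ z - logdet - 0.5 * len(w) * np.log(2 * np.pi))


def krige_mean(coords_obs: np.ndarray, w_obs: np.ndarray,
               coords_new: np.ndarray, params: SpatialFieldParams) -> np.ndarray:
    """Conditional (kriging) mean of the field at new locations.

    ``E[w_new | w_obs] = C_no C_oo^{-1} w_obs`` for a zero-mean field;
    ``w_obs`` may be a matrix of posterior draws (sites on the last axis).
    """
    c_oo = cov_matrix(coords_obs, params)
    c_no = matern_cov(cdist(coords_new, coords_obs), params)
    weights = np.linalg.solve(c_oo, c_no.T)     # (n_obs, n_new)
    return np.asarray(w_obs) @ weights


def simulate_field(coords_km: np.ndarray, params: SpatialFieldParams,
                   rng: np.random.Generator) -> np.ndarray:
    """One draw of the zero-mean Matérn field at the given coordinates."""
    L = chol_cov(coords_km, params)
    return L @ rng.standard_normal(len(coords_km))
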