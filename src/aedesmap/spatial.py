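"""Matérn covariance and penalized-complexity (PC) priors for the spatial field.

The spatial random effect is a stationary Gaussian field with Matérn
covariance of smoothness nu = 1 (the 2-D default of the stochastic PDE
representation, alpha = 2 => nu = alpha - d/2 = 1):

    C(d) = sigma^2 * (kappa d) * K_1(kappa d),   kappa = sqrt(8 nu) / rho

where rho is the "range": the distance at which the correlation has fallen
to roughly 0.1.  PC priors penalise distance from the base model of no
spatial effect and are calibrated through two interpretable tail
statements, P(rho < rho0) = p_rho and P(sigma > sigma0) = p_sigma, giving

    pi(rho)   = (lambda_rho / rho^2) exp(-lambda_rho / rho),
        lambda_rho   = -rho0 * ln(p_rho)
    pi(sigma) = lambda_sigma exp(-lambda_sigma sigma),
        lambda_sigma = -ln(p_sigma) / sigma0
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import kv


def matern_covariance(distances, range_km, sd, nu=1.0, jitter=1e-8):
    """Matérn covariance matrix (or values) at the given distances.

    ``range_km`` follows the correlation-0.1 convention:
    kappa = sqrt(8 nu) / range.  ``C(0) = sd**2`` exactly.  When
    ``distances`` is a square symmetric matrix, ``jitter * sd**2`` is added
    to the diagonal for factorization stability.
    """
    d = np.asarray(distances, dtype=np.float64)
    if range_km <= 0 or sd < 0:
        raise ValueError("range_km must be > 0 and sd >= 0")
    is_matrix = d.ndim == 2 and d.shape[0] == d.shape[1]
    if is_matrix:
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("distance matrix must have zero diagonal")
    cov = sd**2 * matern_kernel(d, range_km, nu=nu)
    if is_matrix:
        cov = cov + jitter * sd**2 * np.eye(d.shape[0])
    return cov


def matern_kernel(d, range_km, nu=1.0):
    """Matérn correlation values at distances ``d`` (no shape checks)."""
    d = np.asarray(d, dtype=np.float64)
    kappa = np.sqrt(8.0 * nu) / range_km
    x = kappa * d
    with np.errstate(invalid="ignore"):
        corr = np.where(x > 0, x * kv(nu, np.maximum(x, 1e-300)), 1.0)
    return np.where(x > 0, corr, 1.0)  # x K_1(x) -> 1 as x -> 0


def matern_correlation(distances, range_km, nu=1.0):
    return matern_covariance(distances, range_km, 1.0, nu=nu, jitter=0.0)


@dataclass(frozen=True)
class PCPriorSpec:
    """PC-prior calibration for the Matérn range and field sd.

    Defaults encode P(range < 10 km) = 0.95 and P(sd > 0.5) = 0.05:
    observations further apart than half the study-area width are unlikely
    to be correlated, and the spatial effect is expected to be small
    relative to the covariate effects.
    """

    range_ref: float = 10.0
    range_prob: float = 0.95
    sd_ref: float = 0.5
    sd_prob: float = 0.05
    rate_range: float = field(init=False)
    rate_sd: float = field(init=False)

    def __post_init__(self):
        if self.range_ref <= 0 or self.sd_ref <= 0:
            raise ValueError("reference values must be positive")
        for p in (self.range_prob, self.sd_prob):
            if not 0 < p < 1:
                raise ValueError("calibration probabilities must be in (0, 1)")
        object.__setattr__(self, "rate_range", -self.range_ref * np.log(self.range_prob))
        object.__setattr__(self, "rate_sd", -np.log(self.sd_prob) / self.sd_ref)

    # -- closed-form densities/CDFs (inverse-exponential in rho, exponential in sigma)

    def range_logpdf(self, rho):
        rho = np.asarray(rho, dtype=np.float64)
        lam = self.rate_range
        return np.where(rho > 0, np.log(lam) - 2 * np.log(rho) - lam / rho, -np.inf)

    def range_pdf(self, rho):
        return np.exp(self.range_logpdf(rho))

    def range_cdf(self, rho):
        rho = np.asarray(rho, dtype=np.float64)
        return np.where(rho > 0, np.exp(-self.rate_range / np.maximum(rho, 1e-300)), 0.0)

    def sd_logpdf(self, sigma):
        sigma = np.asarray(sigma, dtype=np.float64)
        lam = self.rate_sd
        return np.where(sigma >= 0, np.log(lam) - lam * sigma, -np.inf)

    def sd_pdf(self, sigma):
        return np.exp(self.sd_logpdf(sigma))

    def sd_cdf(self, sigma):
        sigma = np.asarray(sigma, dtype=np.float64)
        return np.where(sigma >= 0, -np.expm1(-self.rate_sd * sigma), 0.0)


def pc_prior_rates(range_ref, range_prob, sd_ref, sd_prob) -> PCPriorSpec:
    """Calibrate PC-prior rates from the two tail statements."""
    return PCPriorSpec(range_ref, range_prob, sd_ref, sd_prob)


def pairwise_distances(easting, northing):
    """Euclidean distance matrix for planar km coordinates."""
    xy = np.column_stack([np.asarray(easting, float), np.asarray(northing, float)])
    diff = xy[:, None, :] - xy[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def cross_distances(east_a, north_a, east_b, north_b):
    a = np.column_stack([np.asarray(east_a, float), np.asarray(north_a, float)])
    b = np.column_stack([np.asarray(east_b, float), np.asarray(north_b, float)])
    diff = a[:, None, :] - b[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))
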