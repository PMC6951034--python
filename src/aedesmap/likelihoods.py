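"""Count-family log-likelihoods on the mean scale.

All three families are parameterised by the mean ``mu`` of the count
component so that a single log-linear predictor ``log mu = X beta + u``
serves every family:

* Poisson: ``y ~ Pois(mu)``.
* Negative binomial (mean/size): ``E[y] = mu``, ``Var[y] = mu + mu**2 / size``;
  ``size -> inf`` recovers the Poisson.
* Zero-inflated Poisson: extra mass ``zip_prob`` at zero atop ``Pois(mu)``,
  so ``E[y] = (1 - zip_prob) * mu``.

Implemented with :func:`scipy.special.gammaln` directly (rather than the
frozen scipy distributions) because the samplers evaluate these densities
millions of times on ~5,000-element vectors.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

FAMILIES = ("poisson", "zip", "negbin")


def _validate_counts(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("empty count vector")
    if np.any(y < 0):
        raise ValueError("negative count in response")
    if not np.allclose(y, np.round(y)):
        raise ValueError("non-integer count in response")
    return y.astype(np.float64)


def poisson_logpmf(y, mu):
    y = np.asarray(y, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    return y * np.log(mu) - mu - gammaln(y + 1.0)


def negbin_logpmf(y, mu, size):
    """NB log-pmf with mean ``mu`` and size (dispersion) ``size``."""
    y = np.asarray(y, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    n = float(size)
    return (
        gammaln(y + n)
        - gammaln(n)
        - gammaln(y + 1.0)
        + n * np.log(n / (n + mu))
        + y * np.log(mu / (n + mu))
    )


def zip_logpmf(y, mu, zip_prob):
    """Zero-inflated Poisson log-pmf with structural-zero probability."""
    y = np.asarray(y, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    p0 = float(zip_prob)
    pois = poisson_logpmf(y, mu)
    if p0 == 0.0:
        return pois
    out = np.log1p(-p0) + pois
    at_zero = y == 0
    if np.any(at_zero):
        # log(p0 + (1-p0) e^{pois}) computed stably
        out = np.where(
            at_zero,
            np.logaddexp(np.log(p0), np.log1p(-p0) + pois),
            out,
        )
    return out


def log_likelihood(y, mu, family, nb_size=None, zip_prob=None):
    """Per-observation log-density for one of the three count families.

    Parameters
    ----------
    y : array of non-negative integers
    mu : array of positive means (count-component mean for ZIP)
    family : {"poisson", "zip", "negbin"}
    nb_size : positive float, required for ``family="negbin"``
    zip_prob : probability in [0, 1), required for ``family="zip"``
    """
    y = _validate_counts(y)
    mu = np.asarray(mu, dtype=np.float64)
    if np.any(~np.isfinite(mu)) or np.any(mu <= 0):
        raise ValueError("mu must be positive and finite")
    if family == "poisson":
        return poisson_logpmf(y, mu)
    if family == "negbin":
        if nb_size is None or nb_size <= 0:
            raise ValueError("negbin requires nb_size > 0")
        return negbin_logpmf(y, mu, nb_size)
    if family == "zip":
        if zip_prob is None or not (0 <= zip_prob < 1):
            raise ValueError("zip requires zip_prob in [0, 1)")
        return zip_logpmf(y, mu, zip_prob)
    raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")


def family_mean(mu, family, nb_size=None, zip_prob=None):
    """Marginal mean E[y] given the count-component mean ``mu``."""
    mu = np.asarray(mu, dtype=np.float64)
    if family == "zip":
        return (1.0 - float(zip_prob)) * mu
    return mu


def family_variance(mu, family, nb_size=None, zip_prob=None):
    """Marginal variance Var[y] given the count-component mean ``mu``."""
    mu = np.asarray(mu, dtype=np.float64)
    if family == "poisson":
        return mu
    if family == "negbin":
        return mu + mu**2 / float(nb_size)
    if family == "zip":
        p0 = float(zip_prob)
        return (1.0 - p0) * mu * (1.0 + p0 * mu)
    raise ValueError(f"unknown family {family!r}")


def sample_counts(rng, mu, family, nb_size=None, zip_prob=None):
    """Draw counts from the family at mean ``mu`` (vectorised)."""
    mu = np.asarray(mu, dtype=np.float64)
    if family == "poisson":
        return rng.poisson(mu)
    if family == "negbin":
        n = float(nb_size)
        # Gamma-Poisson mixture: lam ~ Gamma(n, scale=mu/n), y ~ Pois(lam)
        lam = rng.gamma(shape=n, scale=mu / n)
        return rng.poisson(lam)
    if family == "zip":
        p0 = float(zip_prob)
        y = rng.poisson(mu)
        zeros = rng.random(mu.shape) < p0
        y[zeros] = 0
        return y
    raise ValueError(f"unknown family {family!r}")
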