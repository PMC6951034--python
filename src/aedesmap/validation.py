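"""Posterior-predictive checks: simulated-count histograms and scaled residuals.

The fitted model is interrogated by drawing parameter sets from the
posterior (1,000 by default), simulating a complete replicate dataset from
each, and comparing the observed count histogram with the pointwise 2.5–97.5
percentile band of the simulated histograms.  A model that keeps the
observed frequencies inside the band is considered a good predictive fit.
Scaled (Pearson) residuals of the observed data are likewise compared
against the envelope of the residuals of the simulated datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .likelihoods import family_mean, family_variance, sample_counts

logger = logging.getLogger(__name__)


@dataclass
class PredictiveEnsemble:
    """Simulated replicate datasets and the histogram band they imply."""

    sims: np.ndarray  # (n_sims, n_obs) simulated counts
    observed: np.ndarray  # (n_obs,)
    count_values: np.ndarray  # tabulated count values 0..K
    band_lower: np.ndarray  # 2.5th percentile of frequency per count value
    band_upper: np.ndarray  # 97.5th percentile
    observed_freq: np.ndarray

    @property
    def n_sims(self):
        return self.sims.shape[0]

    def band_coverage(self) -> float:
        """Fraction of count bins whose observed frequency is inside the band."""
        inside = (self.observed_freq >= self.band_lower) & (
            self.observed_freq <= self.band_upper
        )
        return float(inside.mean())

    def zero_band_position(self) -> float:
        """Where the observed number of zeros sits within the simulated zeros
        (0 = below all simulations, 1 = above all; near 1 flags too few
        simulated zeros, the rare-species diagnostic)."""
        sim_zeros = (self.sims == 0).sum(axis=1)
        obs_zeros = int((self.observed == 0).sum())
        return float(np.mean(sim_zeros < obs_zeros))


def _tabulate(counts_2d, k_max):
    n_sims = counts_2d.shape[0]
    out = np.zeros((n_sims, k_max + 1), dtype=np.int64)
    for i in range(n_sims):
        c = np.bincount(counts_2d[i][counts_2d[i] <= k_max], minlength=k_max + 1)
        out[i] = c
    return out


def posterior_predictive(results, n_sims=1000, seed=0, exog=None, site_index=None):
    """Simulate ``n_sims`` replicate datasets from posterior parameter draws.

    One parameter set (beta, field, family parameters) is used per replicate;
    if fewer posterior draws than ``n_sims`` are available the draws are
    resampled with replacement (logged).  The histogram band covers count
    values 0..max(observed max, 99th percentile of the simulations).
    """
    model = results.model
    y_obs = model.endog
    X = model.exog if exog is None else np.asarray(exog, float)
    sidx = model.site_index if exog is None else site_index
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 23]))

    total = results._beta_flat.shape[0]
    if n_sims <= total:
        idx = rng.choice(total, size=n_sims, replace=False)
    else:
        logger.info("requested %d sims > %d posterior draws; sampling with replacement", n_sims, total)
        idx = rng.choice(total, size=n_sims, replace=True)

    size_draws, pi_draws = results._fam_params()
    sims = np.empty((n_sims, len(y_obs)), dtype=np.int64)
    for row, d in enumerate(idx):
        eta = X @ results._beta_flat[d]
        if results._u_flat is not None and sidx is not None:
            eta = eta + results._u_flat[d][sidx]
        mu = np.exp(eta)
        sims[row] = sample_counts(
            rng,
            mu,
            model.family,
            nb_size=size_draws[d] if size_draws is not None else None,
            zip_prob=pi_draws[d] if pi_draws is not None else None,
        )

    k_max = int(max(y_obs.max(), np.percentile(sims, 99)))
    table = _tabulate(sims, k_max)
    lower = np.percentile(table, 2.5, axis=0)
    upper = np.percentile(table, 97.5, axis=0)
    obs_freq = np.bincount(y_obs[y_obs <= k_max], minlength=k_max + 1)
    return PredictiveEnsemble(
        sims=sims,
        observed=np.asarray(y_obs),
        count_values=np.arange(k_max + 1),
        band_lower=lower,
        band_upper=upper,
        observed_freq=obs_freq,
    )


@dataclass
class ResidualCheck:
    """Observed Pearson residual quantiles against the simulated envelope."""

    quantile_grid: np.ndarray
    observed_quantiles: np.ndarray
    envelope_lower: np.ndarray
    envelope_upper: np.ndarray
    observed_residuals: np.ndarray
    mean_shift: float  # observed mean residual minus simulated mean residual

    @property
    def flags(self):
        """True where the observed quantile escapes the simulated envelope."""
        return (self.observed_quantiles < self.envelope_lower) | (
            self.observed_quantiles > self.envelope_upper
        )

    @property
    def fraction_outside(self):
        return float(self.flags.mean())


def scaled_residuals(results, y=None, ensemble=None, n_sims=1000, seed=0, quantiles=None):
    """Pearson residuals of observed vs posterior-predictive datasets.

    Residuals are r_i = (y_i - m_i) / sqrt(V(m_i)) with m and V the family
    marginal mean/variance at the posterior-mean fit; the same scaling is
    applied to every simulated dataset so the observed quantiles can be
    placed inside (or outside) the simulated envelope.
    """
    model = results.model
    y = model.endog if y is None else np.asarray(y)
    if ensemble is None:
        ensemble = posterior_predictive(results, n_sims=n_sims, seed=seed)
    quantiles = quantiles if quantiles is not None else np.linspace(2.5, 97.5, 39)

    eta_bar = results.fittedvalues_mean_eta()
    size_draws, pi_draws = results._fam_params()
    kw = dict(
        nb_size=size_draws.mean() if size_draws is not None else None,
        zip_prob=pi_draws.mean() if pi_draws is not None else None,
    )
    mu = np.exp(eta_bar)
    m = family_mean(mu, model.family, **kw)
    sd = np.sqrt(family_variance(mu, model.family, **kw))

    obs_res = (y - m) / sd
    sim_res = (ensemble.sims - m) / sd
    obs_q = np.percentile(obs_res, quantiles)
    sim_q = np.percentile(sim_res, quantiles, axis=1)  # (n_q, n_sims)
    env_lo = np.percentile(sim_q, 2.5, axis=1)
    env_hi = np.percentile(sim_q, 97.5, axis=1)
    mean_shift = float(obs_res.mean() - sim_res.mean())
    return ResidualCheck(
        quantile_grid=np.asarray(quantiles),
        observed_quantiles=obs_q,
        envelope_lower=env_lo,
        envelope_upper=env_hi,
        observed_residuals=obs_res,
        mean_shift=mean_shift,
    )


def plot_predictive_check(ensemble: PredictiveEnsemble, ax=None, max_count=None):
    """Histogram of observed counts with the 95% simulated band (log-x)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    k = len(ensemble.count_values) if max_count is None else min(max_count + 1, len(ensemble.count_values))
    v = ensemble.count_values[:k]
    ax.fill_between(v, ensemble.band_lower[:k], ensemble.band_upper[:k], alpha=0.4, label="95% prediction interval", step="mid")
    ax.plot(v, ensemble.observed_freq[:k], drawstyle="steps-mid", color="k", lw=1, label="observed")
    ax.set_xlabel("count value")
    ax.set_ylabel("frequency")
    ax.set_yscale("symlog")
    ax.legend()
    return ax


def plot_residual_envelope(check: ResidualCheck, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    q = check.quantile_grid
    ax.fill_between(q, check.envelope_lower, check.envelope_upper, alpha=0.4, label="simulated envelope")
    ax.plot(q, check.observed_quantiles, color="k", lw=1, label="observed")
    ax.set_xlabel("residual quantile (%)")
    ax.set_ylabel("scaled residual")
    ax.legend()
    return ax
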