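"""Spike-and-slab Bayesian variable selection for count regressions.

Each candidate coefficient gets a normal-mixture (NMIG-style) prior

    beta_j | gamma_j ~ Normal(0, gamma_j v1 + (1 - gamma_j) v0),
    gamma_j ~ Bernoulli(w),

with a narrow spike (v0 = 0.005^2) and a diffuse slab (v1 = 2.5^2) on the
standardized scale and prior inclusion w = 0.5.  The sampler integrates the
indicator out — beta is drawn under the collapsed two-component mixture
prior by component-wise adaptive Metropolis — and gamma_j is then drawn from
its exact conditional Bernoulli given beta_j each iteration.  The reported
posterior inclusion probability is the Rao-Blackwellized average of
P(gamma_j = 1 | beta_j) over the retained draws, which mixes far better
across spike/slab than alternating (beta | gamma, gamma | beta) updates.

The count likelihood during selection is negative binomial (the final model
family) with the same shrinkage prior on the size as the main model; the
coefficients enter linearly (no smooth terms).  A Gaussian working
likelihood with known noise variance is also supported so the sampler can
be validated against brute-force enumeration of gamma configurations on
tiny conjugate instances.

Selection then follows a two-stage rule: rank candidates by inclusion
probability, restrict to the top k (12 by default), keep at most one lag
per weather variable (the lag with the largest absolute scaled effect), and
return the six with the largest absolute scaled effect sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpikeSlabPrior:
    spike_variance: float = 0.005**2
    slab_variance: float = 2.5**2
    inclusion_prior: float = 0.5

    def __post_init__(self):
        if not 0 < self.spike_variance < self.slab_variance:
            raise ValueError("need 0 < spike_variance < slab_variance")
        if not 0 < self.inclusion_prior < 1:
            raise ValueError("inclusion_prior must be in (0, 1)")


@dataclass
class SelectionResult:
    """Per-candidate inclusion probabilities, scaled effects, and ranks."""

    table: pd.DataFrame  # index: candidate; cols: inclusion_probability, scaled_effect, rank
    chosen: list = field(default_factory=list)

    def __repr__(self):
        return f"SelectionResult(\n{self.table}\nchosen={self.chosen})"


def _mixture_terms(b, prior: SpikeSlabPrior):
    """(log spike density + log(1-w), log slab density + log w) at b."""
    v0, v1, w = prior.spike_variance, prior.slab_variance, prior.inclusion_prior
    l0 = np.log1p(-w) - 0.5 * np.log(2 * np.pi * v0) - 0.5 * b * b / v0
    l1 = np.log(w) - 0.5 * np.log(2 * np.pi * v1) - 0.5 * b * b / v1
    return l0, l1


def _mixture_logprior(b, prior):
    l0, l1 = _mixture_terms(b, prior)
    return np.logaddexp(l0, l1)


def _inclusion_prob(b, prior):
    l0, l1 = _mixture_terms(b, prior)
    return expit(l1 - l0)


def spike_slab_select(
    y,
    X: pd.DataFrame,
    prior: SpikeSlabPrior | None = None,
    n_iter=4000,
    burn_in=1000,
    seed=0,
    family="negbin",
    sigma2=None,
) -> SelectionResult:
    """MCMC spike-and-slab selection over the columns of ``X``.

    Parameters
    ----------
    y : counts (or real responses when ``family="gaussian"``)
    X : DataFrame of standardized candidate columns (no intercept column;
        one is handled internally with a diffuse prior)
    family : "negbin" (default) or "gaussian" (validation mode; requires
        ``sigma2``, the known noise variance)
    """
    prior = prior or SpikeSlabPrior()
    if not n_iter > burn_in >= 0:
        raise ValueError("need n_iter > burn_in >= 0")
    if not isinstance(X, pd.DataFrame):
        raise TypeError("X must be a DataFrame of named candidate columns")
    names = list(X.columns)
    Xm = X.to_numpy(dtype=np.float64)
    n, p = Xm.shape

    sds = Xm.std(axis=0)
    dead = [names[j] for j in range(p) if sds[j] == 0]
    if dead:
        raise ValueError(f"constant/zero candidate column(s): {dead}")
    if np.linalg.matrix_rank(Xm) < p:
        raise ValueError("candidate design is rank deficient (duplicate columns?)")

    y = np.asarray(y)
    if family in ("negbin",):
        if np.any(y < 0) or not np.allclose(y, np.round(y)):
            raise ValueError("counts must be non-negative integers")
        y = y.astype(np.float64)
        from .likelihoods import negbin_logpmf

        def loglik(eta, lsize):
            return float(negbin_logpmf(y, np.exp(eta), np.exp(lsize)).sum())

    elif family == "gaussian":
        if sigma2 is None or sigma2 <= 0:
            raise ValueError("gaussian working likelihood requires sigma2 > 0")
        y = y.astype(np.float64)

        def loglik(eta, lsize):
            return float(-0.5 * np.sum((y - eta) ** 2) / sigma2)

    else:
        raise ValueError(f"unsupported selection family {family!r}")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 11]))
    beta = np.zeros(p)
    if family == "negbin":
        intercept = float(np.log(max(y.mean(), 0.1)))
        m, v = y.mean(), y.var()
        lsize = float(np.log(np.clip(m**2 / max(v - m, 1e-3), 0.05, 50.0)))
    else:
        intercept = float(y.mean())
        lsize = 0.0
    eta = np.full(n, intercept) + Xm @ beta
    ll = loglik(eta, lsize)

    nb_rate = np.log(20.0)

    def lp_lsize(ls):
        return float(np.log(nb_rate / 2.0) - nb_rate * np.exp(-ls / 2.0) - ls / 2.0)

    scale_b = np.full(p, 0.1)
    scale_i, scale_s = 0.05, 0.15
    acc_b = np.zeros(p)
    tri_b = np.zeros(p)
    acc_i = tri_i = acc_s = tri_s = 0.0
    batch = 0

    incl_acc = np.zeros(p)
    beta_acc = np.zeros(p)
    gamma_draws = np.zeros(p)
    kept = 0

    for it in range(n_iter):
        # intercept (diffuse Normal(0, 10^2))
        prop = intercept + scale_i * rng.standard_normal()
        ll_new = loglik(eta + (prop - intercept), lsize)
        tri_i += 1
        if np.log(rng.random()) < ll_new - ll - 0.5 * (prop**2 - intercept**2) / 100.0:
            eta = eta + (prop - intercept)
            intercept, ll = prop, ll_new
            acc_i += 1

        for j in rng.permutation(p):
            if rng.random() < 0.25:
                # independence proposal from the mixture prior itself: the
                # prior terms cancel, so the likelihood ratio decides.  This
                # jumps between spike and slab even when the random walk's
                # adapted step is locked to one component's width.
                comp_sd = np.sqrt(
                    prior.slab_variance
                    if rng.random() < prior.inclusion_prior
                    else prior.spike_variance
                )
                prop = comp_sd * rng.standard_normal()
                eta_new = eta + Xm[:, j] * (prop - beta[j])
                ll_new = loglik(eta_new, lsize)
                if np.log(rng.random()) < ll_new - ll:
                    beta[j], eta, ll = prop, eta_new, ll_new
                continue
            prop = beta[j] + scale_b[j] * rng.standard_normal()
            eta_new = eta + Xm[:, j] * (prop - beta[j])
            ll_new = loglik(eta_new, lsize)
            dpr = _mixture_logprior(prop, prior) - _mixture_logprior(beta[j], prior)
            tri_b[j] += 1
            if np.log(rng.random()) < ll_new - ll + dpr:
                beta[j], eta, ll = prop, eta_new, ll_new
                acc_b[j] += 1

        if family == "negbin":
            prop = lsize + scale_s * rng.standard_normal()
            ll_new = loglik(eta, prop)
            tri_s += 1
            if np.log(rng.random()) < ll_new - ll + lp_lsize(prop) - lp_lsize(lsize):
                lsize, ll = prop, ll_new
                acc_s += 1

        if not np.isfinite(ll):
            raise RuntimeError(f"divergent chain: non-finite log-posterior at iteration {it}")

        if it < burn_in and (it + 1) % 25 == 0:
            batch += 1
            step = 1.0 / np.sqrt(batch)
            rate = np.where(tri_b > 0, acc_b / tri_b, 0.44)
            scale_b *= np.exp(step * (rate - 0.44))
            if tri_i:
                scale_i *= np.exp(step * (acc_i / tri_i - 0.44))
            if tri_s:
                scale_s *= np.exp(step * (acc_s / tri_s - 0.44))
            acc_b[:] = 0
            tri_b[:] = 0
            acc_i = tri_i = acc_s = tri_s = 0.0

        if it >= burn_in:
            pj = _inclusion_prob(beta, prior)
            incl_acc += pj
            beta_acc += beta
            gamma_draws += (rng.random(p) < pj).astype(float)  # explicit gamma | beta draw
            kept += 1

    inclusion = incl_acc / kept
    effects = beta_acc / kept
    table = pd.DataFrame(
        {"inclusion_probability": inclusion, "scaled_effect": effects}, index=names
    )
    table["rank"] = table["inclusion_probability"].rank(ascending=False, method="min").astype(int)
    table = table.sort_values("inclusion_probability", ascending=False)
    return SelectionResult(table=table)


def choose_top_six(result: SelectionResult, weather_groups=None, top_k=12, n_select=6):
    """Two-stage choice: inclusion-probability shortlist, then effect size.

    Within each weather group only the lag with the largest |scaled effect|
    stays in contention.  From the ``top_k`` candidates by inclusion
    probability, the ``n_select`` with the largest |scaled effect| are
    chosen; ties at the boundary break alphabetically (logged).
    """
    tab = result.table.copy()
    weather_groups = weather_groups or {}
    drop = []
    for base, cols in weather_groups.items():
        cols = [c for c in cols if c in tab.index]
        if len(cols) <= 1:
            continue
        best = tab.loc[cols, "scaled_effect"].abs().idxmax()
        drop.extend(c for c in cols if c != best)
    tab = tab.drop(index=drop)

    shortlist = tab.sort_values("inclusion_probability", ascending=False).head(top_k)
    ordered = shortlist.assign(_abs=shortlist["scaled_effect"].abs()).sort_values(
        ["_abs", "inclusion_probability"], ascending=[False, False]
    )
    if len(ordered) > n_select:
        cut = ordered["_abs"].iloc[n_select - 1]
        at_cut = ordered[ordered["_abs"] == cut]
        if len(at_cut) > 1:
            # deterministic alphabetical tie-break at the boundary
            above = list(ordered.index[ordered["_abs"] > cut])
            tied_sorted = at_cut.sort_index()
            logger.info(
                "tie at selection boundary broken alphabetically: %s", list(tied_sorted.index)
            )
            chosen = (above + list(tied_sorted.index))[:n_select]
        else:
            chosen = list(ordered.index[:n_select])
    else:
        if len(ordered) < n_select:
            logger.warning("only %d candidates available (< %d)", len(ordered), n_select)
        chosen = list(ordered.index)
    result.chosen = chosen
    return chosen
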