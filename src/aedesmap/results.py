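"""Posterior results container: estimates, intervals, DIC, diagnostics.

A :class:`SpatialCountResults` wraps the posterior draws produced by
:meth:`~aedesmap.model.SpatialCountModel.fit`.  Coefficient point estimates
are posterior means on the log incidence-rate-ratio scale (exp(beta)
multiplies the expected count per 1-SD covariate increase); uncertainty is
reported as equal-tailed 95% credible intervals.  Model comparison uses the
deviance information criterion DIC = D-bar + pD with pD = D-bar - D(theta-bar),
the plug-in theta-bar being the posterior mean of the linear predictor and
the family parameters.  Fit adequacy uses the Pearson overdispersion
statistic sum((y - m)^2 / V) / (N - p) per posterior draw.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .likelihoods import family_mean, family_variance, log_likelihood


class SpatialCountResults:
    """Posterior draws plus derived summaries for one fitted model."""

    def __init__(self, model, samples: dict, diagnostics: dict, mcmc_info: dict):
        self.model = model
        self.samples = samples
        self.diagnostics = diagnostics
        self.mcmc_info = mcmc_info
        C, D, p = samples["beta"].shape
        self.n_chains, self.n_draws = C, D
        self._beta_flat = samples["beta"].reshape(C * D, p)
        self._u_flat = samples["u"].reshape(C * D, -1) if "u" in samples else None
        self._dic_cache = None

    # ------------------------------------------------------------ basic
    @property
    def exog_names(self):
        return self.model.exog_names

    def _flat(self, key):
        return self.samples[key].reshape(-1)

    @property
    def params(self) -> pd.Series:
        """Posterior mean coefficients (log-IRR scale)."""
        return pd.Series(self._beta_flat.mean(axis=0), index=self.exog_names)

    @property
    def bse(self) -> pd.Series:
        """Posterior standard deviations of the coefficients."""
        return pd.Series(self._beta_flat.std(axis=0, ddof=1), index=self.exog_names)

    def conf_int(self, alpha=0.05) -> pd.DataFrame:
        lo, hi = np.percentile(
            self._beta_flat, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0
        )
        return pd.DataFrame({"lower": lo, "upper": hi}, index=self.exog_names)

    def important_terms(self, alpha=0.05) -> pd.Series:
        """Bayesian 'statistically important' flags: 95% CI excludes zero."""
        ci = self.conf_int(alpha)
        return (ci["lower"] > 0) | (ci["upper"] < 0)

    def hyper_summary(self) -> pd.DataFrame:
        """Posterior summaries for range, sd, NB size, zero inflation."""
        rows = {}
        for key in ("range_km", "sd", "nb_size", "zip_prob"):
            if key in self.samples:
                x = self._flat(key)
                rows[key] = {
                    "mean": x.mean(),
                    "median": np.median(x),
                    "2.5%": np.percentile(x, 2.5),
                    "97.5%": np.percentile(x, 97.5),
                }
        return pd.DataFrame(rows).T

    @property
    def range_posterior_median(self):
        return float(np.median(self._flat("range_km"))) if "range_km" in self.samples else None

    # ------------------------------------------------------------ draws
    def linear_predictor_draws(self, exog=None, site_index=None, chunk=None):
        """Iterate (eta_draws, slice) chunks of shape (k, n_obs)."""
        X = self.model.exog if exog is None else np.asarray(exog, float)
        sidx = self.model.site_index if exog is None else site_index
        n_total = self._beta_flat.shape[0]
        chunk = chunk or 250
        for start in range(0, n_total, chunk):
            sl = slice(start, min(start + chunk, n_total))
            eta = self._beta_flat[sl] @ X.T
            if self._u_flat is not None and sidx is not None:
                eta = eta + self._u_flat[sl][:, sidx]
            yield eta, sl

    def fittedvalues_mean_eta(self):
        """Posterior mean of the linear predictor per observation."""
        n = len(self.model.endog)
        acc = np.zeros(n)
        total = 0
        for eta, sl in self.linear_predictor_draws():
            acc += eta.sum(axis=0)
            total += eta.shape[0]
        return acc / total

    @property
    def fittedvalues(self):
        """Posterior mean of mu = exp(eta) per observation."""
        n = len(self.model.endog)
        acc = np.zeros(n)
        total = 0
        for eta, sl in self.linear_predictor_draws():
            acc += np.exp(eta).sum(axis=0)
            total += eta.shape[0]
        return acc / total

    def _fam_params(self, sl=slice(None)):
        size = self._flat("nb_size")[sl] if "nb_size" in self.samples else None
        pi0 = self._flat("zip_prob")[sl] if "zip_prob" in self.samples else None
        return size, pi0

    # ------------------------------------------------------------ DIC
    def dic(self):
        """(DIC, pD) from the conditional deviance given the latent field."""
        if self._dic_cache is not None:
            return self._dic_cache
        y = self.model.endog
        fam = self.model.family
        dev_draws = []
        for eta, sl in self.linear_predictor_draws():
            size, pi0 = self._fam_params(sl)
            for i in range(eta.shape[0]):
                ll = log_likelihood(
                    y,
                    np.exp(eta[i]),
                    fam,
                    nb_size=size[i] if size is not None else None,
                    zip_prob=pi0[i] if pi0 is not None else None,
                ).sum()
                dev_draws.append(-2.0 * ll)
        dev_draws = np.array(dev_draws)
        if np.any(~np.isfinite(dev_draws)):
            raise ValueError("non-finite deviance draws")
        eta_bar = self.fittedvalues_mean_eta()
        size, pi0 = self._fam_params()
        ll_bar = log_likelihood(
            y,
            np.exp(eta_bar),
            fam,
            nb_size=size.mean() if size is not None else None,
            zip_prob=pi0.mean() if pi0 is not None else None,
        ).sum()
        d_bar = dev_draws.mean()
        d_hat = -2.0 * ll_bar
        pd_eff = d_bar - d_hat
        self._dic_cache = (float(d_bar + pd_eff), float(pd_eff))
        return self._dic_cache

    # ------------------------------------------------ overdispersion
    def overdispersion(self, y=None):
        """Pearson overdispersion statistic: posterior mean and 95% interval.

        Per draw: sum((y - m)^2 / V(m)) / (N - p) with m, V the family
        marginal mean/variance and p the number of fixed-effect parameters.
        """
        y = self.model.endog if y is None else np.asarray(y)
        n_obs = len(y)
        p = self.model.exog.shape[1]
        if n_obs <= p:
            raise ValueError("need more observations than fixed-effect parameters")
        fam = self.model.family
        stats = []
        for eta, sl in self.linear_predictor_draws():
            size, pi0 = self._fam_params(sl)
            mu = np.exp(eta)
            for i in range(eta.shape[0]):
                kw = dict(
                    nb_size=size[i] if size is not None else None,
                    zip_prob=pi0[i] if pi0 is not None else None,
                )
                m = family_mean(mu[i], fam, **kw)
                v = family_variance(mu[i], fam, **kw)
                stats.append(np.sum((y - m) ** 2 / v) / (n_obs - p))
        stats = np.array(stats)
        return float(stats.mean()), (float(np.percentile(stats, 2.5)), float(np.percentile(stats, 97.5)))

    # ------------------------------------------------------------ summary
    def summary(self) -> str:
        ci = self.conf_int()
        imp = self.important_terms()
        lines = []
        title = f"{self.model.family} count model" + (" + Matérn spatial effect" if self.model.spatial else "")
        lines.append(title)
        lines.append("=" * len(title))
        lines.append(
            f"n obs: {len(self.model.endog)}   chains: {self.n_chains}   draws/chain: {self.n_draws}"
        )
        dic, pd_eff = self.dic()
        lines.append(f"DIC: {dic:.2f}   pD: {pd_eff:.2f}")
        od, (od_lo, od_hi) = self.overdispersion()
        lines.append(f"Pearson overdispersion: {od:.2f} (95% CI {od_lo:.2f}-{od_hi:.2f})")
        lines.append("")
        header = f"{'term':<34}{'mean':>8}{'sd':>8}{'2.5%':>9}{'97.5%':>9}  {'important':>9}{'R-hat':>7}"
        lines.append(header)
        lines.append("-" * len(header))
        for name in self.exog_names:
            rhat = self.diagnostics.get(f"beta[{name}]", {}).get("rhat", np.nan)
            lines.append(
                f"{name:<34}{self.params[name]:>8.3f}{self.bse[name]:>8.3f}"
                f"{ci.loc[name, 'lower']:>9.3f}{ci.loc[name, 'upper']:>9.3f}"
                f"  {'yes' if imp[name] else 'no':>9}{rhat:>7.3f}"
            )
        hyper = self.hyper_summary()
        if len(hyper):
            lines.append("")
            for key, row in hyper.iterrows():
                lines.append(
                    f"{key:<34}{row['mean']:>8.3f}{'':>8}{row['2.5%']:>9.3f}{row['97.5%']:>9.3f}"
                )
        return "\n".join(lines)

    # ------------------------------------------------------- persistence
    def save(self, outdir):
        """Write draws + metadata as CSV/JSON so a fit can be reloaded."""
        import json
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        C, D, p = self.samples["beta"].shape
        flat = pd.DataFrame(self._beta_flat, columns=self.exog_names)
        flat.insert(0, "chain", np.repeat(np.arange(C), D))
        for key in ("range_km", "sd", "nb_size", "zip_prob"):
            if key in self.samples:
                flat[key] = self._flat(key)
        flat.to_csv(outdir / "posterior_draws.csv", index=False)
        if self._u_flat is not None:
            pd.DataFrame(
                self._u_flat, columns=[f"u{j}" for j in range(self._u_flat.shape[1])]
            ).to_csv(outdir / "field_draws.csv", index=False)
        meta = {
            "exog_names": self.exog_names,
            "family": self.model.family,
            "spatial": self.model.spatial,
            "mcmc_info": self.mcmc_info,
            "diagnostics": self.diagnostics,
        }
        (outdir / "fit_meta.json").write_text(json.dumps(meta, indent=2))
        return outdir

    @classmethod
    def load(cls, fit_dir, endog, exog, site_index=None, coords=None):
        """Rebuild results from :meth:`save` output plus the fitting data."""
        import json
        from pathlib import Path

        from .model import SpatialCountModel

        fit_dir = Path(fit_dir)
        meta = json.loads((fit_dir / "fit_meta.json").read_text())
        flat = pd.read_csv(fit_dir / "posterior_draws.csv")
        C = int(flat["chain"].max()) + 1
        D = len(flat) // C
        model = SpatialCountModel(
            endog,
            exog,
            site_index=site_index,
            coords=coords,
            family=meta["family"],
            spatial=meta["spatial"],
        )
        samples = {"beta": flat[meta["exog_names"]].to_numpy().reshape(C, D, -1)}
        for key in ("range_km", "sd", "nb_size", "zip_prob"):
            if key in flat.columns:
                samples[key] = flat[key].to_numpy().reshape(C, D)
        ufile = fit_dir / "field_draws.csv"
        if ufile.exists():
            samples["u"] = pd.read_csv(ufile).to_numpy().reshape(C, D, -1)
        return cls(model, samples, meta["diagnostics"], meta["mcmc_info"])

    # ------------------------------------------------------- delegations
    def posterior_predictive(self, n_sims=1000, seed=0, exog=None, site_index=None):
        from .validation import posterior_predictive

        return posterior_predictive(self, n_sims=n_sims, seed=seed, exog=exog, site_index=site_index)

    def scaled_residuals(self, y=None, ensemble=None, n_sims=1000, seed=0):
        from .validation import scaled_residuals

        return scaled_residuals(self, y=y, ensemble=ensemble, n_sims=n_sims, seed=seed)

    def interpolate_field(self, grid_east, grid_north, n_draws=200, seed=0):
        from .prediction import interpolate_field

        return interpolate_field(self, grid_east, grid_north, n_draws=n_draws, seed=seed)

    def predict_weekly(self, grid, covariates_by_week, n_draws=200, seed=0, include_field=True):
        from .prediction import predict_weekly

        return predict_weekly(
            self, grid, covariates_by_week, n_draws=n_draws, seed=seed, include_field=include_field
        )
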