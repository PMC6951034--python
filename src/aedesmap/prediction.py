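"""Gridded weekly predictions and spatial-field interpolation (risk maps).

The fitted spatial effect is a site-level Gaussian field; predictions at
unobserved grid cells use the conditional (kriging) distribution of a
Matérn field given the site values, evaluated per posterior draw so that
hyperparameter uncertainty propagates.  Weekly expected counts on a 1-km
grid combine the kriged field with weekly-aggregated weather covariates
(daily lags applied first, then averaged within ISO weeks) transformed with
the frozen training standardization constants; predicted counts are drawn
from the fitted family, giving per-cell means with 95% intervals and a
citywide weekly series.  The predicted count at a cell assumes one
trap-night per cell-week (no offset).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .likelihoods import sample_counts
from .spatial import cross_distances, matern_kernel

logger = logging.getLogger(__name__)

_JITTER = 1e-8


def make_grid(extent_km, spacing_km=1.0, origin=(0.0, 0.0)) -> pd.DataFrame:
    """Regular cell-centre grid covering a square extent."""
    xs = np.arange(origin[0] + spacing_km / 2, origin[0] + extent_km, spacing_km)
    ys = np.arange(origin[1] + spacing_km / 2, origin[1] + extent_km, spacing_km)
    ee, nn = np.meshgrid(xs, ys)
    return pd.DataFrame(
        {
            "cell_id": [f"C{i:04d}" for i in range(ee.size)],
            "easting_km": ee.ravel(),
            "northing_km": nn.ravel(),
        }
    )


def _kriging_weights(site_dists, cross_d, range_km, jitter=_JITTER):
    """Conditional weights W and residual correlation diag for one draw."""
    S = site_dists.shape[0]
    R_ss = matern_kernel(site_dists, range_km) + jitter * np.eye(S)
    R_gs = matern_kernel(cross_d, range_km)
    W = np.linalg.solve(R_ss, R_gs.T).T  # (G, S)
    resid = 1.0 - np.einsum("gs,gs->g", W, R_gs)
    return W, np.maximum(resid, 0.0)


def interpolate_field(results, grid_east, grid_north, n_draws=200, seed=0):
    """Posterior mean and sd of the spatial effect at grid locations.

    Per posterior draw d the field at the grid is Gaussian with mean
    W_d u_d and variance sigma_d^2 (1 - diag(W_d R_gs')); means and
    variances are mixed over draws.  Far from every site the mean reverts
    to 0 and the sd to the posterior mean of sigma.
    """
    model = results.model
    if not model.spatial:
        raise ValueError("interpolate_field requires a spatial fit")
    ge = np.asarray(grid_east, float)
    gn = np.asarray(grid_north, float)
    site_d = model.distances
    cross_d = cross_distances(ge, gn, model.coords[:, 0], model.coords[:, 1])

    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 31]))
    total = results._u_flat.shape[0]
    idx = rng.choice(total, size=min(n_draws, total), replace=False)

    rho_draws = results._flat("range_km")
    sig_draws = results._flat("sd")
    if np.all(cross_d.min(axis=1) > 100 * np.median(rho_draws)):
        logger.warning(
            "all grid points are >100x the posterior range from every site; "
            "check that grid coordinates are in km"
        )

    mean_acc = np.zeros(len(ge))
    m2_acc = np.zeros(len(ge))
    var_acc = np.zeros(len(ge))
    for d in idx:
        W, resid = _kriging_weights(site_d, cross_d, rho_draws[d])
        m = W @ results._u_flat[d]
        mean_acc += m
        m2_acc += m**2
        var_acc += sig_draws[d] ** 2 * resid
    k = len(idx)
    mean = mean_acc / k
    var = var_acc / k + m2_acc / k - mean**2
    return pd.DataFrame(
        {"easting_km": ge, "northing_km": gn, "field_mean": mean, "field_sd": np.sqrt(np.maximum(var, 0))}
    )


@dataclass
class PredictionSurface:
    """Weekly gridded predictions plus the interpolated spatial effect."""

    table: pd.DataFrame  # week, cell_id, easting_km, northing_km, mean, lower, upper
    field: pd.DataFrame  # cell_id, field_mean, field_sd
    n_draws: int

    def weekly_series(self, how="sum") -> pd.DataFrame:
        """Citywide weekly series: per-week sum or mean over cells."""
        if how not in ("sum", "mean"):
            raise ValueError("how must be 'sum' or 'mean'")
        agg = {"mean": how, "lower": how, "upper": how}
        out = self.table.groupby("week").agg(agg).reset_index()
        return out

    def week_map(self, week) -> pd.DataFrame:
        sub = self.table[self.table["week"] == week]
        if sub.empty:
            raise KeyError(f"week {week!r} not in surface")
        return sub.reset_index(drop=True)

    def peak_week(self, how="sum"):
        series = self.weekly_series(how)
        return int(series.loc[series["mean"].idxmax(), "week"])

    def to_geojson(self, week, path=None):
        """Cell-centre point features for one week (planar km coordinates)."""
        sub = self.week_map(week)
        features = [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [row.easting_km, row.northing_km]},
                "properties": {
                    "cell_id": row.cell_id,
                    "week": int(week),
                    "mean": float(row.mean_count) if hasattr(row, "mean_count") else float(row.mean),
                    "lower": float(row.lower),
                    "upper": float(row.upper),
                },
            }
            for row in sub.itertuples()
        ]
        obj = {"type": "FeatureCollection", "features": features}
        if path is not None:
            with open(path, "w") as fh:
                json.dump(obj, fh)
        return obj


def weekly_weather_design(weather: pd.DataFrame, terms, design_info, weeks=None) -> pd.DataFrame:
    """Weekly standardized weather-term values from a daily series.

    For a term like ``temperature_lag1`` the daily series is shifted by 7
    days first, averaged within each ISO week, then transformed with the
    *training* standardization constants.  Interaction terms are products of
    their parents' weekly standardized values.  Non-weather terms are set to
    0 (the training mean).  Returns a DataFrame indexed by ISO week.
    """
    daily = weather.set_index("date")
    iso = pd.DatetimeIndex(daily.index).isocalendar()
    parents = [t for t in terms if " x " not in t]
    out = {}
    week_index = None
    for term in parents:
        matched = None
        for base in daily.columns:
            for lag in (0, 1, 2):
                if term == f"{base}_lag{lag}":
                    matched = (base, lag)
        if matched is None:
            out[term] = None  # site-level: training mean (0) by default
            continue
        base, lag = matched
        shifted = daily[base].shift(7 * lag)
        wk = shifted.groupby([iso["year"].to_numpy(), iso["week"].to_numpy()]).mean().dropna()
        z = design_info.transform(term, wk.to_numpy())
        idx = [w for (_, w) in wk.index]
        ser = pd.Series(z, index=idx)
        ser = ser.groupby(level=0).mean()  # merge split ISO weeks across years
        out[term] = ser
        week_index = ser.index if week_index is None else week_index.intersection(ser.index)
    if week_index is None:
        raise ValueError("no weather terms found in the term list")
    if weeks is not None:
        week_index = pd.Index([w for w in week_index if w in set(weeks)])
    df = pd.DataFrame(index=week_index)
    for term in parents:
        ser = out[term]
        df[term] = 0.0 if ser is None else ser.reindex(week_index).to_numpy()
    for term in terms:
        if " x " in term:
            a, b = term.split(" x ")
            for parent in (a, b):
                if parent not in df.columns:
                    raise KeyError(f"interaction {term!r} needs parent {parent!r}")
            df[term] = df[a] * df[b]
    df.index.name = "week"
    return df[list(terms)]


def predict_weekly(results, grid: pd.DataFrame, covariates_by_week: pd.DataFrame, n_draws=200, seed=0, include_field=True):
    """Weekly predicted counts with 95% intervals at every grid cell.

    ``covariates_by_week`` is indexed by week and holds one column per
    model term (intercept excluded); columns of ``grid`` whose names match
    model terms override the weekly value cell-wise (site-level covariates
    such as land cover).  A missing term raises, naming it.
    """
    model = results.model
    terms = [t for t in model.exog_names if t != "intercept"]
    for t in terms:
        if t not in covariates_by_week.columns and t not in grid.columns:
            raise KeyError(f"missing model term {t!r} in weekly covariates/grid")

    G = len(grid)
    weeks = list(covariates_by_week.index)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 37]))
    total = results._beta_flat.shape[0]
    idx = rng.choice(total, size=min(n_draws, total), replace=False)

    if include_field and model.spatial:
        field_df = interpolate_field(
            results, grid["easting_km"].to_numpy(), grid["northing_km"].to_numpy(), n_draws=min(n_draws, total), seed=seed
        )
        cross_d = cross_distances(
            grid["easting_km"].to_numpy(), grid["northing_km"].to_numpy(), model.coords[:, 0], model.coords[:, 1]
        )
        rho_draws = results._flat("range_km")
        sig_draws = results._flat("sd")
    else:
        field_df = pd.DataFrame(
            {"cell_id": grid["cell_id"], "field_mean": np.zeros(G), "field_sd": np.zeros(G)}
        )

    size_draws, pi_draws = results._fam_params()
    beta = results._beta_flat
    name_to_col = {n: j for j, n in enumerate(model.exog_names)}

    # cell-level covariate matrix template (terms x cells)
    cell_over = {t: grid[t].to_numpy(float) for t in terms if t in grid.columns}

    sims = np.zeros((len(idx), len(weeks), G))
    for di, d in enumerate(idx):
        b = beta[d]
        if include_field and model.spatial:
            W, resid = _kriging_weights(model.distances, cross_d, rho_draws[d])
            u_cell = W @ results._u_flat[d] + np.sqrt(sig_draws[d] ** 2 * resid) * rng.standard_normal(G)
        else:
            u_cell = np.zeros(G)
        for wi, week in enumerate(weeks):
            eta = np.full(G, b[name_to_col["intercept"]])
            for t in terms:
                val = cell_over[t] if t in cell_over else covariates_by_week.loc[week, t]
                eta = eta + b[name_to_col[t]] * val
            eta = eta + u_cell
            mu = np.exp(eta)
            sims[di, wi] = sample_counts(
                rng,
                mu,
                model.family,
                nb_size=size_draws[d] if size_draws is not None else None,
                zip_prob=pi_draws[d] if pi_draws is not None else None,
            )

    mean = sims.mean(axis=0)
    lower = np.percentile(sims, 2.5, axis=0)
    upper = np.percentile(sims, 97.5, axis=0)
    rows = []
    for wi, week in enumerate(weeks):
        for g in range(G):
            rows.append(
                {
                    "week": week,
                    "cell_id": grid["cell_id"].iloc[g],
                    "easting_km": grid["easting_km"].iloc[g],
                    "northing_km": grid["northing_km"].iloc[g],
                    "mean": mean[wi, g],
                    "lower": lower[wi, g],
                    "upper": upper[wi, g],
                }
            )
    table = pd.DataFrame(rows)
    field_df = field_df.assign(cell_id=grid["cell_id"].to_numpy())
    return PredictionSurface(table=table, field=field_df, n_draws=len(idx))


def expected_weekly_mean(results, covariates_by_week: pd.DataFrame, grid=None):
    """Posterior-mean expected count per week at covariates (no sampling).

    Deterministic counterpart of :func:`predict_weekly` used for
    monotonicity-style checks: E[mu] per week averaged over posterior
    coefficient draws, field at 0.
    """
    model = results.model
    terms = [t for t in model.exog_names if t != "intercept"]
    beta = results._beta_flat
    name_to_col = {n: j for j, n in enumerate(model.exog_names)}
    out = {}
    for week in covariates_by_week.index:
        eta = beta[:, name_to_col["intercept"]].copy()
        for t in terms:
            if t not in covariates_by_week.columns:
                raise KeyError(f"missing model term {t!r}")
            eta = eta + beta[:, name_to_col[t]] * covariates_by_week.loc[week, t]
        out[week] = float(np.exp(eta).mean())
    return pd.Series(out, name="expected_count")


def plot_weekly_series(surface: PredictionSurface, how="sum", ax=None, smooth_frac=0.25):
    """Weekly prediction curve with a loess-style smoother overlay."""
    import matplotlib.pyplot as plt

    series = surface.weekly_series(how)
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    ax.fill_between(series["week"], series["lower"], series["upper"], alpha=0.3, label="95% interval")
    ax.plot(series["week"], series["mean"], "o", ms=3, label="predicted")
    # local quadratic smoother as the trend overlay
    x = series["week"].to_numpy(float)
    y = series["mean"].to_numpy(float)
    span = max(3, int(smooth_frac * len(x)))
    smoothed = np.array(
        [
            np.poly1d(np.polyfit(x[max(0, i - span) : i + span], y[max(0, i - span) : i + span], 2))(x[i])
            for i in range(len(x))
        ]
    )
    ax.plot(x, smoothed, "--", label="trend")
    ax.set_xlabel("ISO week")
    ax.set_ylabel(f"predicted count ({how} over cells)")
    ax.legend()
    return ax
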