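"""Kriging interpolation and weekly gridded prediction checks."""

import numpy as np
import pandas as pd
import pytest

import aedesmap as am
from aedesmap.prediction import (
    expected_weekly_mean,
    interpolate_field,
    make_grid,
    predict_weekly,
    weekly_weather_design,
)
from aedesmap.pipeline import data_info_for


class TestInterpolation:
    def test_exact_at_site_locations(self, small_spatial_fit):
        data, res = small_spatial_fit
        out = interpolate_field(res, data.layout.easting, data.layout.northing, n_draws=400, seed=1)
        u_mean = res._u_flat.mean(axis=0)
        np.testing.assert_allclose(out["field_mean"], u_mean, atol=0.05)
        # at a site the kriging residual variance vanishes, so the reported
        # sd reduces to the posterior sd of the site effect itself
        u_sd = res._u_flat.std(axis=0)
        np.testing.assert_allclose(out["field_sd"], u_sd, atol=0.05)

    def test_reverts_to_prior_far_away(self, small_spatial_fit):
        data, res = small_spatial_fit
        out = interpolate_field(res, np.array([500.0]), np.array([500.0]), n_draws=150, seed=2)
        assert abs(out["field_mean"].iloc[0]) < 0.05
        sigma = res.hyper_summary().loc["sd", "mean"]
        assert out["field_sd"].iloc[0] == pytest.approx(sigma, rel=0.25)

    def test_sd_nondecreasing_along_transect(self, small_spatial_fit):
        data, res = small_spatial_fit
        x0, y0 = data.layout.easting[0], data.layout.northing[0]
        # march away from the nearest site along +x beyond the layout
        xs = x0 + 30.0 + np.linspace(0, 20, 15)
        out = interpolate_field(res, xs, np.full(15, y0), n_draws=150, seed=3)
        sd = out["field_sd"].to_numpy()
        assert np.all(np.diff(sd) > -1e-6)

    def test_symmetric_points_get_identical_field(self):
        """Collinear sites: mirrored grid points are equidistant from every
        site and must receive identical interpolated values."""
        rng = np.random.default_rng(3)
        y = rng.poisson(3.0, 300)
        X = pd.DataFrame({"a": rng.standard_normal(300)})
        sidx = np.repeat([0, 1, 2], 100)
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
        res = am.SpatialCountModel(
            y, X, site_index=sidx, coords=coords, family="poisson", spatial=True
        ).fit(draws=300, warmup=300, chains=2, seed=4, rhat_action="warn")
        out = interpolate_field(res, np.array([1.0, 1.0]), np.array([1.0, -1.0]), n_draws=100, seed=5)
        assert out["field_mean"].iloc[0] == pytest.approx(out["field_mean"].iloc[1], abs=1e-10)
        assert out["field_sd"].iloc[0] == pytest.approx(out["field_sd"].iloc[1], abs=1e-10)

    def test_requires_spatial_fit(self, small_nb_fit):
        with pytest.raises(ValueError, match="spatial"):
            interpolate_field(small_nb_fit, np.array([0.0]), np.array([0.0]))


@pytest.fixture(scope="module")
def surface(small_spatial_fit):
    data, res = small_spatial_fit
    terms = [c for c in data.design.columns if c not in ("site_id", "date")]
    grid = make_grid(5.0, spacing_km=2.5)
    week_design = weekly_weather_design(data.weather, terms, data_info_for(data, terms))
    return data, res, predict_weekly(res, grid, week_design, n_draws=120, seed=6)


class TestWeeklyPrediction:
    def test_surface_invariants(self, surface):
        _, _, surf = surface
        t = surf.table
        assert (t["lower"] <= t["upper"]).all()
        assert (t["lower"] <= t["mean"]).all()
        series = surf.weekly_series("sum")
        assert len(series) == t["week"].nunique()
        assert surf.peak_week() in set(t["week"])

    def test_geojson_roundtrip(self, surface, tmp_path):
        _, _, surf = surface
        peak = surf.peak_week()
        obj = surf.to_geojson(peak, tmp_path / "map.geojson")
        import json

        loaded = json.loads((tmp_path / "map.geojson").read_text())
        assert loaded["type"] == "FeatureCollection"
        assert len(loaded["features"]) == len(surf.week_map(peak))

    def test_mean_covariates_give_intercept_prediction(self, small_spatial_fit):
        data, res = small_spatial_fit
        terms = [c for c in data.design.columns if c not in ("site_id", "date")]
        wk = pd.DataFrame(0.0, index=[1], columns=terms)
        expected = expected_weekly_mean(res, wk)
        icpt = res._beta_flat[:, res.exog_names.index("intercept")]
        assert expected.iloc[0] == pytest.approx(np.exp(icpt).mean(), rel=1e-9)

    def test_monotone_in_positive_coefficient(self, small_spatial_fit):
        data, res = small_spatial_fit
        terms = [c for c in data.design.columns if c not in ("site_id", "date")]
        # humidity has a strongly positive posterior-mean coefficient
        assert res.params["humidity_lag0"] > 0
        wk = pd.DataFrame(0.0, index=[1, 2], columns=terms)
        wk.loc[2, "humidity_lag0"] = 1.0
        expected = expected_weekly_mean(res, wk)
        assert expected.loc[2] > expected.loc[1]

    def test_missing_term_named(self, small_spatial_fit):
        data, res = small_spatial_fit
        grid = make_grid(5.0, spacing_km=2.5)
        wk = pd.DataFrame(0.0, index=[1], columns=["humidity_lag0"])
        with pytest.raises(KeyError, match="trees"):
            predict_weekly(res, grid, wk, n_draws=10, seed=7)

    def test_interval_coverage_on_held_out_replicate(self, small_spatial_fit):
        """95% predictive intervals cover fresh counts from the same model."""
        data, res = small_spatial_fit
        ens = res.posterior_predictive(n_sims=300, seed=8)
        lo = np.percentile(ens.sims, 2.5, axis=0)
        hi = np.percentile(ens.sims, 97.5, axis=0)
        fresh = am.build_scenario(
            am.GeneratorConfig(
                n_sites=30, obs_mean=40, seed=999,
                intercept=data.config.intercept, true_beta=data.config.true_beta,
                true_range_km=data.config.true_range_km, nb_size=data.config.nb_size,
            )
        )
        m = min(len(fresh.y), len(lo))
        cover = np.mean((fresh.y[:m] >= lo[:m]) & (fresh.y[:m] <= hi[:m]))
        assert cover > 0.85


class TestWeeklyDesign:
    def test_lag_shifts_daily_series_before_weekly_mean(self, small_spatial_fit):
        data, _ = small_spatial_fit
        terms = ["temperature_lag1", "humidity_lag0"]
        info = data_info_for(data, terms)
        wk = weekly_weather_design(data.weather, terms, info)
        assert list(wk.columns) == terms
        assert not wk.isna().any().any()

    def test_interaction_needs_parents(self, small_spatial_fit):
        data, _ = small_spatial_fit
        info = data_info_for(data, ["temperature_lag1"])
        with pytest.raises(KeyError):
            weekly_weather_design(
                data.weather, ["temperature_lag1", "temperature_lag1 x humidity_lag0"], info
            )
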