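"""Model fitting: oracle agreement, DIC, overdispersion, error contracts."""

import numpy as np
import pandas as pd
import pytest

import aedesmap as am
from aedesmap.diagnostics import ConvergenceError
from aedesmap.results import SpatialCountResults


@pytest.fixture(scope="module")
def poisson_data():
    rng = np.random.default_rng(21)
    n = 2500
    X = pd.DataFrame({"a": rng.standard_normal(n), "b": rng.standard_normal(n)})
    eta = 1.0 + 0.5 * X["a"].to_numpy() - 0.3 * X["b"].to_numpy()
    y = rng.poisson(np.exp(eta))
    return y, X


class TestOracleAgreement:
    def test_poisson_map_matches_irls(self, poisson_data):
        """Our posterior mode vs statsmodels' iteratively-reweighted ML."""
        import statsmodels.api as sm

        y, X = poisson_data
        model = am.SpatialCountModel(y, X, family="poisson", spatial=False)
        ours = model.map_estimate()["beta"]
        ref = sm.GLM(y, sm.add_constant(X), family=sm.families.Poisson()).fit().params
        np.testing.assert_allclose(ours, ref.to_numpy(), atol=5e-4)

    def test_poisson_posterior_concentrates_on_mle(self, poisson_data):
        import statsmodels.api as sm

        y, X = poisson_data
        model = am.SpatialCountModel(y, X, family="poisson", spatial=False)
        res = model.fit(draws=700, warmup=700, chains=2, seed=2, rhat_action="warn")
        ref = sm.GLM(y, sm.add_constant(X), family=sm.families.Poisson()).fit().params
        np.testing.assert_allclose(res.params.to_numpy(), ref.to_numpy(), atol=0.02)

    def test_negbin_matches_ml_fit(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(22)
        n = 3000
        X = pd.DataFrame({"a": rng.standard_normal(n)})
        mu = np.exp(1.0 + 0.5 * X["a"].to_numpy())
        y = rng.poisson(rng.gamma(2.0, mu / 2.0))
        model = am.SpatialCountModel(y, X, family="negbin", spatial=False)
        res = model.fit(draws=700, warmup=700, chains=2, seed=3, rhat_action="warn")
        ref = sm.NegativeBinomial(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(res.params.to_numpy(), ref.params.iloc[:2], atol=0.03)
        # statsmodels alpha = 1/size
        assert res.hyper_summary().loc["nb_size", "mean"] == pytest.approx(
            1 / ref.params.iloc[2], rel=0.15
        )


class TestOverdispersionStatistic:
    def test_poisson_on_poisson_near_one(self, poisson_data):
        y, X = poisson_data
        model = am.SpatialCountModel(y, X, family="poisson", spatial=False)
        res = model.fit(draws=500, warmup=500, chains=2, seed=4, rhat_action="warn")
        point, (lo, hi) = res.overdispersion()
        assert point == pytest.approx(1.0, abs=0.07)
        assert lo < point < hi

    def test_poisson_model_on_overdispersed_data(self):
        rng = np.random.default_rng(23)
        n = 1500
        X = pd.DataFrame({"a": rng.standard_normal(n)})
        mu = np.exp(1.0 + 0.4 * X["a"].to_numpy())
        y = rng.poisson(rng.gamma(0.7, mu / 0.7))
        model = am.SpatialCountModel(y, X, family="poisson", spatial=False)
        res = model.fit(draws=400, warmup=400, chains=2, seed=5, rhat_action="warn")
        point, _ = res.overdispersion()
        assert point > 1.5


class TestDIC:
    def test_degenerate_posterior_zero_pd(self, poisson_data):
        y, X = poisson_data
        model = am.SpatialCountModel(y, X, family="poisson", spatial=False)
        beta = np.tile(model.map_estimate()["beta"], (2, 60, 1))
        res = SpatialCountResults(model, {"beta": beta}, {}, {})
        dic, pd_eff = res.dic()
        assert pd_eff == pytest.approx(0.0, abs=1e-6)

    def test_pd_counts_effective_parameters(self, poisson_data):
        y, X = poisson_data
        model = am.SpatialCountModel(y, X, family="poisson", spatial=False)
        res = model.fit(draws=500, warmup=500, chains=2, seed=6, rhat_action="warn")
        _, pd_eff = res.dic()
        assert pd_eff == pytest.approx(3.0, abs=1.0)  # three fixed effects


class TestZIP:
    def test_zero_inflation_recovered(self):
        rng = np.random.default_rng(24)
        n = 2500
        X = pd.DataFrame({"a": rng.standard_normal(n)})
        mu = np.exp(1.2 + 0.3 * X["a"].to_numpy())
        y = rng.poisson(mu)
        y[rng.random(n) < 0.3] = 0
        model = am.SpatialCountModel(y, X, family="zip", spatial=False)
        res = model.fit(draws=600, warmup=600, chains=2, seed=7, rhat_action="warn")
        assert res.hyper_summary().loc["zip_prob", "mean"] == pytest.approx(0.3, abs=0.05)
        assert res.params["a"] == pytest.approx(0.3, abs=0.05)


class TestSpatial:
    def test_vanishing_field_matches_nonspatial(self):
        data = am.aegypti_scenario(seed=31, n_sites=15, obs_mean=40, true_sd=0.0)
        terms = [c for c in data.design.columns if c not in ("site_id", "date")]
        coords = np.column_stack([data.layout.easting, data.layout.northing])
        spatial = am.SpatialCountModel(
            data.y, data.design[terms], site_index=data.site_index, coords=coords,
            family="negbin", spatial=True,
        ).fit(draws=500, warmup=500, chains=2, seed=8, rhat_action="warn")
        plain = am.SpatialCountModel(
            data.y, data.design[terms], family="negbin", spatial=False
        ).fit(draws=500, warmup=500, chains=2, seed=9, rhat_action="warn")
        np.testing.assert_allclose(
            spatial.params.to_numpy(), plain.params.to_numpy(), atol=0.08
        )
        # and the field sd posterior shrinks toward its base model
        assert spatial.hyper_summary().loc["sd", "median"] < 0.2

    def test_spatial_effect_lowers_dic_when_present(self, small_spatial_fit):
        data, res = small_spatial_fit
        terms = [c for c in data.design.columns if c not in ("site_id", "date")]
        plain = am.SpatialCountModel(
            data.y, data.design[terms], family="negbin", spatial=False
        ).fit(draws=400, warmup=400, chains=2, seed=10, rhat_action="warn")
        assert res.dic()[0] < plain.dic()[0]


class TestContracts:
    def test_convergence_error_carries_table(self, poisson_data):
        y, X = poisson_data
        model = am.SpatialCountModel(y, X, family="poisson", spatial=False)
        with pytest.raises(ConvergenceError) as exc:
            # a deliberately unattainable threshold exercises the failure path
            model.fit(draws=60, warmup=60, chains=2, seed=11, rhat_threshold=0.5)
        assert exc.value.table is not None

    def test_single_chain_rejected(self, poisson_data):
        y, X = poisson_data
        with pytest.raises(ValueError, match="chains"):
            am.SpatialCountModel(y, X, family="poisson", spatial=False).fit(chains=1)

    def test_spatial_needs_three_sites(self):
        y = np.array([1, 2, 0, 3])
        X = pd.DataFrame({"a": [0.1, -0.5, 0.3, 0.2]})
        with pytest.raises(ValueError, match="sites"):
            am.SpatialCountModel(
                y, X, site_index=[0, 0, 1, 1], coords=np.array([[0.0, 0.0], [1.0, 1.0]]),
                family="negbin", spatial=True,
            )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            am.SpatialCountModel(np.array([1, -2]), np.ones((2, 1)), family="poisson", spatial=False)

    def test_rank_deficient_design_rejected(self):
        y = np.array([1, 2, 3, 4])
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 4.0, 6.0, 8.0]})
        with pytest.raises(ValueError, match="rank"):
            am.SpatialCountModel(y, X, family="poisson", spatial=False)

    def test_compare_models_needs_two_specs(self):
        with pytest.raises(ValueError):
            am.compare_models(np.array([1, 2]), pd.DataFrame({"a": [0.1, 0.2]}), [am.ModelSpec("poisson", False)])

    def test_summary_renders(self, small_spatial_fit):
        _, res = small_spatial_fit
        text = res.summary()
        assert "DIC" in text and "range_km" in text and "intercept" in text
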