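"""Standardization, lag construction, correlation screening, interactions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aedesmap.preprocess import (
    add_interaction,
    build_lags,
    destandardize,
    flag_correlated_pairs,
    standardize,
    standardize_with,
)


class TestStandardize:
    def test_basic_example(self):
        z, mean, sd = standardize([1.0, 2.0, 3.0])
        np.testing.assert_allclose(z, [-1.0, 0.0, 1.0])
        assert (mean, sd) == (2.0, 1.0)

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(0)
        z0, _, _ = standardize(rng.standard_normal(100))
        z1, m, s = standardize(z0)
        np.testing.assert_allclose(z1, z0, atol=1e-12)
        assert m == pytest.approx(0, abs=1e-12)
        assert s == pytest.approx(1, abs=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            standardize([5.0, 5.0, 5.0])

    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=50).filter(
            lambda xs: np.std(xs) > 1e-6
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip(self, xs):
        z, mean, sd = standardize(xs)
        np.testing.assert_allclose(destandardize(z, mean, sd), xs, rtol=1e-9, atol=1e-6)

    def test_frozen_constants_for_prediction(self):
        z, mean, sd = standardize([10.0, 20.0, 30.0])
        new = standardize_with([40.0], mean, sd)
        assert new[0] == pytest.approx((40 - mean) / sd)


class TestLags:
    @pytest.fixture
    def doy_series(self):
        dates = pd.date_range("2017-01-01", "2017-12-31")
        return pd.Series(np.arange(1, len(dates) + 1), index=dates, name="temp")

    def test_lag_definition_single_daily_value(self, doy_series):
        obs = [pd.Timestamp("2017-01-01") + pd.Timedelta(days=99)]  # day 100
        lags = build_lags(doy_series, obs, lags=(0, 1, 2))
        assert lags.loc[0, "temp_lag0"] == 100
        assert lags.loc[0, "temp_lag1"] == 93
        assert lags.loc[0, "temp_lag2"] == 86

    def test_constant_series_gives_identical_columns(self):
        dates = pd.date_range("2017-01-01", periods=60)
        s = pd.Series(7.0, index=dates, name="x")
        lags = build_lags(s, dates[20:30])
        assert lags.stack().nunique() == 1

    def test_lag0_equals_same_day(self, doy_series):
        obs = doy_series.index[50:60]
        lags = build_lags(doy_series, obs, lags=(0,))
        np.testing.assert_array_equal(lags["temp_lag0"], doy_series.loc[obs])

    def test_date_before_series_start_raises(self, doy_series):
        with pytest.raises(ValueError, match="2016-12"):
            build_lags(doy_series, [pd.Timestamp("2017-01-05")], lags=(2,))


class TestCorrelationScreen:
    def test_perfect_negative_pair(self):
        a = np.arange(10.0)
        df = pd.DataFrame({"A": a, "B": -a})
        pairs = flag_correlated_pairs(df)
        assert pairs == [("A", "B", pytest.approx(-1.0))]

    def test_independent_columns_unflagged(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.standard_normal((500, 4)), columns=list("wxyz"))
        assert flag_correlated_pairs(df, threshold=0.5) == []

    def test_generated_weather_pair_flagged(self):
        from aedesmap.synthetic import generate_weather

        w = generate_weather("2017-01-01", "2017-12-31", seed=1)
        pairs = flag_correlated_pairs(w[["temperature", "humidity"]], threshold=0.4)
        assert len(pairs) == 1
        assert pairs[0][2] > 0.4

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            flag_correlated_pairs(pd.DataFrame({"a": [1, 2], "b": [2, 1]}))


class TestInteraction:
    def test_elementwise_product(self):
        df = pd.DataFrame({"A": [-1.0, 0.0, 1.0], "B": [1.0, 1.0, 1.0]})
        out = add_interaction(df, "A", "B")
        np.testing.assert_allclose(out["A x B"], [-1.0, 0.0, 1.0])
        assert list(out.columns) == ["A", "B", "A x B"]

    def test_not_restandardized(self):
        rng = np.random.default_rng(1)
        a, _, _ = standardize(rng.standard_normal(200))
        b, _, _ = standardize(0.8 * a + rng.standard_normal(200))
        out = add_interaction(pd.DataFrame({"A": a, "B": b}), "A", "B")
        # correlated parents give the product a mean near their correlation
        assert abs(out["A x B"].mean()) > 0.3

    def test_duplicate_rejected(self):
        df = pd.DataFrame({"A": [1.0, 2.0], "B": [0.0, 1.0]})
        out = add_interaction(df, "A", "B")
        with pytest.raises(ValueError, match="already present"):
            add_interaction(out, "B", "A")

    def test_missing_column(self):
        with pytest.raises(KeyError):
            add_interaction(pd.DataFrame({"A": [1.0, 2.0]}), "A", "C")


class TestDesignIO:
    def test_csv_sidecar_round_trip(self, tmp_path):
        from aedesmap.preprocess import build_design, load_design, save_design

        rng = np.random.default_rng(5)
        raw = pd.DataFrame(
            {"trees": rng.uniform(0, 1, 30), "temperature_lag1": rng.normal(22, 6, 30)}
        )
        design, info = build_design(raw)
        save_design(design, info, tmp_path / "design.csv")
        loaded, info2 = load_design(tmp_path / "design.csv")
        pd.testing.assert_frame_equal(design, loaded, check_exact=False)
        assert info2.means == pytest.approx(info.means)
        assert info2.lag_tags == {"temperature_lag1": "lag1"}
        # frozen constants reproduce the original values
        np.testing.assert_allclose(
            info2.inverse("trees", loaded["trees"]), raw["trees"], rtol=1e-9
        )
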