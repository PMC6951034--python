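"""Spike-and-slab selection: signal detection, calibration, choice rule."""

import itertools

import numpy as np
import pandas as pd
import pytest

from aedesmap.selection import (
    SelectionResult,
    SpikeSlabPrior,
    choose_top_six,
    spike_slab_select,
)


def exact_gaussian_inclusion(y, X, prior, sigma2, intercept_var=100.0):
    """Brute-force enumeration oracle for the conjugate Gaussian model.

    Marginalising beta (variance v1 where gamma_j=1, else v0) gives
    y ~ N(0, sigma2 I + X D X'); inclusion probabilities follow from the
    normalized marginal likelihoods over all 2^p gamma configurations.
    """
    n, p = X.shape
    Xa = np.column_stack([np.ones(n), X])
    logws = []
    configs = list(itertools.product([0, 1], repeat=p))
    for gamma in configs:
        var = np.concatenate([[intercept_var], np.where(gamma, prior.slab_variance, prior.spike_variance)])
        cov = sigma2 * np.eye(n) + (Xa * var) @ Xa.T
        sign, logdet = np.linalg.slogdet(cov)
        quad = y @ np.linalg.solve(cov, y)
        loglik = -0.5 * (logdet + quad)
        k = sum(gamma)
        logprior = k * np.log(prior.inclusion_prior) + (p - k) * np.log(1 - prior.inclusion_prior)
        logws.append(loglik + logprior)
    logws = np.array(logws)
    w = np.exp(logws - logws.max())
    w /= w.sum()
    incl = np.zeros(p)
    for weight, gamma in zip(w, configs):
        incl += weight * np.array(gamma)
    return incl


class TestSampler:
    def test_strong_signal_detected_in_nb_counts(self):
        rng = np.random.default_rng(7)
        n = 2000
        X = pd.DataFrame(rng.standard_normal((n, 10)), columns=[f"v{i}" for i in range(10)])
        mu = np.exp(0.8 + 0.5 * X["v0"].to_numpy())
        y = rng.poisson(rng.gamma(2.0, mu / 2.0))
        res = spike_slab_select(y, X, n_iter=2500, burn_in=800, seed=3)
        tab = res.table
        assert tab.loc["v0", "inclusion_probability"] > 0.9
        nulls = tab.drop("v0")["inclusion_probability"]
        assert nulls.median() < 0.3

    def test_all_null_design(self):
        rng = np.random.default_rng(8)
        n = 800
        X = pd.DataFrame(rng.standard_normal((n, 6)), columns=[f"n{i}" for i in range(6)])
        y = rng.poisson(2.0, n)
        res = spike_slab_select(y, X, n_iter=1500, burn_in=500, seed=4)
        assert (res.table["inclusion_probability"] < 0.9).all()

    def test_matches_enumeration_oracle_on_tiny_gaussian(self):
        rng = np.random.default_rng(9)
        n, p = 40, 3
        X = rng.standard_normal((n, p))
        y = 0.8 * X[:, 0] + rng.standard_normal(n)
        prior = SpikeSlabPrior(spike_variance=0.05**2, slab_variance=1.0, inclusion_prior=0.5)
        exact = exact_gaussian_inclusion(y, X, prior, sigma2=1.0)
        res = spike_slab_select(
            y, pd.DataFrame(X, columns=list("abc")), prior=prior,
            n_iter=12000, burn_in=2000, seed=5, family="gaussian", sigma2=1.0,
        )
        np.testing.assert_allclose(
            res.table.sort_index()["inclusion_probability"], exact, atol=0.06
        )

    def test_no_information_limit_returns_prior_weight(self):
        # with an (effectively) flat likelihood the inclusion probability
        # must revert to the prior w
        rng = np.random.default_rng(10)
        X = pd.DataFrame({"a": rng.standard_normal(30)})
        y = rng.standard_normal(30)
        res = spike_slab_select(
            y, X, n_iter=20000, burn_in=2000, seed=6, family="gaussian", sigma2=1e8
        )
        assert res.table.loc["a", "inclusion_probability"] == pytest.approx(0.5, abs=0.05)

    def test_column_order_invariance(self):
        rng = np.random.default_rng(11)
        n = 600
        X = pd.DataFrame(rng.standard_normal((n, 4)), columns=list("abcd"))
        mu = np.exp(0.5 + 0.4 * X["b"].to_numpy())
        y = rng.poisson(mu)
        r1 = spike_slab_select(y, X, n_iter=2000, burn_in=600, seed=12)
        r2 = spike_slab_select(y, X[list("dcba")], n_iter=2000, burn_in=600, seed=12)
        p1 = r1.table.sort_index()["inclusion_probability"]
        p2 = r2.table.sort_index()["inclusion_probability"]
        np.testing.assert_allclose(p1, p2, atol=0.1)

    def test_zero_column_rejected(self):
        X = pd.DataFrame({"ok": [1.0, 2.0, 0.5, 1.5], "dead": [0.0, 0.0, 0.0, 0.0]})
        with pytest.raises(ValueError, match="dead"):
            spike_slab_select(np.array([1, 2, 0, 1]), X, n_iter=10, burn_in=2)

    def test_negative_counts_rejected(self):
        X = pd.DataFrame({"a": [0.1, -0.2, 0.3]})
        with pytest.raises(ValueError):
            spike_slab_select(np.array([1, -1, 2]), X, n_iter=10, burn_in=2)

    def test_iteration_contract(self):
        X = pd.DataFrame({"a": [0.1, -0.2, 0.3]})
        with pytest.raises(ValueError):
            spike_slab_select(np.array([1, 1, 2]), X, n_iter=10, burn_in=10)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame(rng.standard_normal((200, 3)), columns=list("xyz"))
        y = rng.poisson(2.0, 200)
        a = spike_slab_select(y, X, n_iter=600, burn_in=200, seed=42)
        b = spike_slab_select(y, X, n_iter=600, burn_in=200, seed=42)
        pd.testing.assert_frame_equal(a.table, b.table)


def _make_result(rows):
    tab = pd.DataFrame(rows).set_index("name")
    tab["rank"] = tab["inclusion_probability"].rank(ascending=False, method="min").astype(int)
    return SelectionResult(table=tab)


class TestChoice:
    def test_best_lag_per_weather_group(self):
        rows = [
            {"name": "temp_lag0", "inclusion_probability": 0.9, "scaled_effect": 0.1},
            {"name": "temp_lag1", "inclusion_probability": 0.8, "scaled_effect": -0.3},
            {"name": "temp_lag2", "inclusion_probability": 0.85, "scaled_effect": 0.2},
            {"name": "trees", "inclusion_probability": 0.7, "scaled_effect": 0.4},
        ]
        res = _make_result(rows)
        chosen = choose_top_six(res, {"temp": ["temp_lag0", "temp_lag1", "temp_lag2"]})
        assert "temp_lag1" in chosen
        assert "temp_lag0" not in chosen and "temp_lag2" not in chosen

    def test_fewer_than_six_returns_all(self):
        rows = [
            {"name": n, "inclusion_probability": p, "scaled_effect": e}
            for n, p, e in [("a", 0.9, 0.5), ("b", 0.8, 0.2), ("c", 0.1, 0.05)]
        ]
        chosen = choose_top_six(_make_result(rows), {})
        assert chosen == ["a", "b", "c"]

    def test_alphabetical_tie_break_at_boundary(self):
        rows = [{"name": f"big{i}", "inclusion_probability": 0.9, "scaled_effect": 1.0 - 0.1 * i}
                for i in range(5)]
        rows += [
            {"name": "zeta", "inclusion_probability": 0.8, "scaled_effect": 0.3},
            {"name": "alpha", "inclusion_probability": 0.7, "scaled_effect": 0.3},
        ]
        chosen = choose_top_six(_make_result(rows), {})
        assert len(chosen) == 6
        assert "alpha" in chosen and "zeta" not in chosen
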