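import numpy as np
import pandas as pd
import pytest

import aedesmap as am


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170101)


@pytest.fixture(scope="session")
def small_nb_fit():
    """Non-spatial NB fit to its own generating model (n=1200, 2 covariates)."""
    rng = np.random.default_rng(314)
    n = 1200
    X = pd.DataFrame({"a": rng.standard_normal(n), "b": rng.standard_normal(n)})
    eta = 0.8 + 0.5 * X["a"].to_numpy() - 0.3 * X["b"].to_numpy()
    mu = np.exp(eta)
    lam = rng.gamma(1.5, mu / 1.5)
    y = rng.poisson(lam)
    model = am.SpatialCountModel(y, X, family="negbin", spatial=False)
    res = model.fit(draws=600, warmup=600, chains=2, seed=11, rhat_action="warn")
    return res


@pytest.fixture(scope="session")
def small_spatial_fit():
    """Spatial NB fit on a reduced abundant-species scenario."""
    data = am.aegypti_scenario(seed=5, n_sites=30, obs_mean=40)
    terms = [c for c in data.design.columns if c not in ("site_id", "date")]
    coords = np.column_stack([data.layout.easting, data.layout.northing])
    model = am.SpatialCountModel(
        data.y, data.design[terms], site_index=data.site_index, coords=coords,
        family="negbin", spatial=True,
    )
    res = model.fit(draws=500, warmup=500, chains=2, seed=13, rhat_action="warn")
    return data, res
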