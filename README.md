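# aedesmap

Bayesian spatio-temporal modelling of *Aedes* mosquito trap counts.

Urban vector-control programmes run trap networks (e.g. BG-Sentinel traps
for *Aedes aegypti* and *Ae. albopictus*) and need to know **where** and
**when** mosquito counts will peak, and **which** environmental drivers —
land cover, socioeconomic context, lagged weather — explain them.
`aedesmap` implements the full analysis pipeline for this problem:
spike-and-slab predictor selection, count-family selection by DIC, a
spatial negative-binomial mixed model with penalized-complexity priors,
posterior-predictive validation, and weekly 1-km gridded prediction maps.
Because municipal trap data are rarely shareable, the package ships a
synthetic-data generator that reproduces the statistical structure of a
one-year, ~51-site urban surveillance campaign, so every stage is testable
end to end.

## The model

Counts $y_i$ at site $s(i)$ on day $t(i)$ follow a hierarchical count
regression with log link:

$$y_i \sim \mathrm{NB}(\mu_i, n), \qquad
\log \mu_i = \beta_0 + \mathbf{x}_i^\top \boldsymbol\beta + u(s_i)$$

* $\mathbf{x}_i$ — standardized covariates: site-level land cover / SES
  variables, daily weather at lag 0/1/2 weeks (the single daily value 0, 7
  or 14 days before the observation), and products of standardized parents
  as interactions.  Each $\beta_j$ is a log incidence rate ratio per 1-SD
  increase.
* $u$ — a stationary Gaussian field over sites with Matérn($\nu=1$)
  covariance $C(d) = \sigma^2 (\kappa d) K_1(\kappa d)$,
  $\kappa = \sqrt{8}/\rho$; the range $\rho$ is the distance at which
  correlation drops to ≈ 0.1.
* Penalized-complexity priors calibrated by
  $P(\rho < 10\,\mathrm{km}) = 0.95$ and $P(\sigma > 0.5) = 0.05$;
  Normal(0, 10²) on coefficients; PC-style shrinkage of the NB size toward
  the Poisson base model.
* Alternative families: Poisson and zero-inflated Poisson, compared by
  DIC; fit adequacy via the Pearson overdispersion statistic and a
  1,000-replicate posterior-predictive simulation study.

Inference is exact MCMC (adaptive Metropolis + elliptical slice sampling
on the whitened field, with interweaved centred/non-centred hyperparameter
updates), not a Laplace approximation — ~50 sites keep the dense-GP
formulation cheap.

## Worked example

Fit the spatial NB model to a synthetic abundant-species dataset generated
with published coefficient estimates as ground truth:

```python
import numpy as np
import aedesmap as am

data = am.aegypti_scenario(seed=1)          # 51 sites, ~5,000 trap-nights
terms = [c for c in data.design.columns if c not in ("site_id", "date")]
coords = np.column_stack([data.layout.easting, data.layout.northing])

model = am.SpatialCountModel(
    data.y, data.design[terms], site_index=data.site_index, coords=coords,
    family="negbin", spatial=True,
)
res = model.fit(draws=2500, warmup=2000, chains=2, seed=1)
print(res.summary())
```

```
negbin count model + Matérn spatial effect
==========================================
n obs: 4991   chains: 2   draws/chain: 2500
DIC: 27092.64   pD: 47.97
Pearson overdispersion: 1.01 (95% CI 0.95-1.07)

term                                  mean      sd     2.5%    97.5%  important  R-hat
--------------------------------------------------------------------------------------
intercept                            1.633   0.044    1.542    1.721        yes  1.001
trees                                0.373   0.044    0.285    0.462        yes  1.010
water                               -0.040   0.046   -0.131    0.053         no  1.016
built_before_1979                    0.111   0.044    0.023    0.196        yes  1.018
humidity_lag0                        0.437   0.015    0.409    0.466        yes  1.001
irradiance_lag0                      0.549   0.018    0.516    0.585        yes  1.001
temperature_lag1                    -0.223   0.017   -0.257   -0.189        yes  1.001
temperature_lag1 x humidity_lag0    -0.073   0.015   -0.102   -0.043        yes  1.002

range_km                             0.650            0.147    1.491
sd                                   0.272            0.212    0.346
```

Reading it: a 1-SD rise in same-day humidity multiplies the expected trap
count by exp(0.437) ≈ 1.55 (generating truth 0.46); lag-1 temperature is
inverse (hot semi-arid regime); the spatial effect is short-ranged (posterior
range 0.65 km against a generating 0.9 km) and modest (σ ≈ 0.27).  "important"
marks coefficients whose 95% credible interval excludes zero.  The Pearson
overdispersion ≈ 1 confirms the NB family matches the NB-generated data.

Posterior-predictive validation and risk maps:

```python
ens = res.posterior_predictive(n_sims=1000, seed=1)
print(ens.band_coverage())        # 0.970 -> observed histogram inside the
                                  # 95% simulation band in 97% of count bins

from aedesmap.prediction import make_grid, weekly_weather_design
from aedesmap.pipeline import data_info_for
grid = make_grid(10.0, spacing_km=1.0)
wk = weekly_weather_design(data.weather, terms, data_info_for(data, terms))
surface = res.predict_weekly(grid, wk, n_draws=200, seed=1)
surface.peak_week()               # ISO week of the citywide predicted peak
```

The same workflow runs from the shell: `aedesmap simulate | select | fit |
validate | predict`, or end-to-end via `aedesmap run config.yaml`.

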