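"""Synthetic trap-count datasets with the structure the analysis assumes.

The real surveillance data (one year of BG-Sentinel trap counts for two
*Aedes* species at ~51 sites in a ~10x10 km urban extent, with land-cover /
socioeconomic covariates per site and daily weather shared across a 1-km
grid) are not publicly deposited, so every downstream stage is exercised on
data from this module instead.  The generator draws

* uniformly placed sites with unbalanced per-site observation schedules
  (mean 100 trap-nights, minimum 30 — the retention rule's lower bound),
* seasonal daily weather with autocorrelated noise and a positive
  temperature-humidity association (target Spearman rho ~ 0.61),
* standard-normal site covariates (covariates enter the models standardized,
  so only their standardized distribution matters),
* one Matérn(nu=1) spatial field draw per dataset, constant over the year,
* counts from a Poisson / zero-inflated-Poisson / negative-binomial family
  with log-linear mean  log mu = beta0 + x' beta + u(site).

Two ready-made scenarios reproduce the two species regimes with the
published fitted coefficients as generating truths: an abundant species
(~18% zeros) and a rare one (~84% zeros).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .preprocess import add_interaction, build_lags, interaction_name, standardize
from .spatial import matern_covariance, pairwise_distances

WEATHER_VARS = ("temperature", "humidity", "irradiance", "precipitation")

#: Generating truths for the abundant-species scenario (log-IRR scale,
#: standardized covariates). Site-level land-cover/SES effects plus daily
#: weather at the stated lags and the temperature-humidity interaction.
AEGYPTI_TRUTH = {
    "intercept": 1.59,
    "trees": 0.34,
    "water": -0.01,
    "built_before_1979": 0.09,
    "humidity_lag0": 0.46,
    "irradiance_lag0": 0.52,
    "temperature_lag1": -0.21,
    interaction_name("temperature_lag1", "humidity_lag0"): -0.08,
}
AEGYPTI_RANGE_KM = 0.9
AEGYPTI_NB_SIZE = 1.5

#: Rare-species scenario: low intercept (high zero fraction), strong
#: negative urbanization effects, lag-2 humidity and lag-1 temperature.
ALBOPICTUS_TRUTH = {
    "intercept": -1.50,
    "impervious": -0.41,
    "grass": -0.25,
    "built_before_1969": 0.00,
    "population_density": -0.80,
    "humidity_lag2": 0.55,
    "temperature_lag1": -0.50,
    interaction_name("impervious", "grass"): 0.42,
    interaction_name("temperature_lag1", "humidity_lag2"): -0.13,
}
ALBOPICTUS_RANGE_KM = 1.0
ALBOPICTUS_NB_SIZE = 0.8

#: Spatial-field marginal sd used by both scenarios: not printed in the
#: source analysis; chosen once as a value plausible under the PC prior
#: statement P(sd > 0.5) = 0.05 ("spatial effect small relative to the
#: covariate effects").
DEFAULT_FIELD_SD = 0.3


@dataclass
class SiteLayout:
    """Trap-site layout: ids, planar km coordinates, per-site schedule."""

    site_id: np.ndarray
    easting: np.ndarray
    northing: np.ndarray
    n_obs: np.ndarray

    def __post_init__(self):
        self.site_id = np.asarray(self.site_id)
        self.easting = np.asarray(self.easting, float)
        self.northing = np.asarray(self.northing, float)
        self.n_obs = np.asarray(self.n_obs, int)
        if len(set(self.site_id.tolist())) != len(self.site_id):
            raise ValueError("site ids must be unique")
        if np.any(~np.isfinite(self.easting)) or np.any(~np.isfinite(self.northing)):
            raise ValueError("non-finite coordinate")
        d = self.distances()
        if np.any(d[~np.eye(len(d), dtype=bool)] <= 0):
            raise ValueError("pairwise distances must be positive")

    def __len__(self):
        return len(self.site_id)

    def distances(self):
        return pairwise_distances(self.easting, self.northing)

    def to_frame(self):
        return pd.DataFrame(
            {
                "site_id": self.site_id,
                "easting_km": self.easting,
                "northing_km": self.northing,
                "n_obs": self.n_obs,
            }
        )


@dataclass
class GeneratorConfig:
    """Everything needed to draw one synthetic dataset.

    ``true_beta`` maps design-column names to log-IRR coefficients on the
    standardized scale; the intercept is separate.  Defaults are the
    abundant-species study conditions.
    """

    n_sites: int = 51
    extent_km: float = 10.0
    start_date: str = "2017-01-01"
    end_date: str = "2017-12-31"
    intercept: float = AEGYPTI_TRUTH["intercept"]
    true_beta: dict = field(
        default_factory=lambda: {k: v for k, v in AEGYPTI_TRUTH.items() if k != "intercept"}
    )
    true_range_km: float = AEGYPTI_RANGE_KM
    true_sd: float = DEFAULT_FIELD_SD
    family: str = "negbin"
    nb_size: float = AEGYPTI_NB_SIZE
    zip_prob: float = 0.0
    obs_mean: float = 100.0
    obs_min: int = 30
    temp_humidity_corr: float = 0.61
    seed: int = 0

    def __post_init__(self):
        if self.true_range_km <= 0:
            raise ValueError("true_range_km must be > 0")
        if self.true_sd < 0:
            raise ValueError("true_sd must be >= 0")
        if not 0 <= self.zip_prob < 1:
            raise ValueError("zip_prob must be in [0, 1)")
        if self.nb_size <= 0:
            raise ValueError("nb_size must be > 0")
        if self.family not in ("poisson", "zip", "negbin"):
            raise ValueError(f"unknown family {self.family!r}")


def _rng(seed, stream):
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), stream]))


def generate_sites(n_sites, extent_km, obs_mean=100.0, obs_min=30, seed=0) -> SiteLayout:
    """Uniformly placed sites in a square extent with unbalanced schedules.

    Per-site observation counts are Poisson(``obs_mean``) truncated below at
    ``obs_min`` (sparser sites would have been discarded upstream).
    """
    if n_sites < 2:
        raise ValueError("need at least 2 sites (spatial covariance undefined)")
    if extent_km <= 0:
        raise ValueError("extent_km must be positive")
    rng = _rng(seed, 1)
    east = rng.uniform(0, extent_km, n_sites)
    north = rng.uniform(0, extent_km, n_sites)
    n_obs = np.maximum(rng.poisson(obs_mean, n_sites), obs_min)
    ids = np.array([f"S{i:03d}" for i in range(n_sites)])
    return SiteLayout(ids, east, north, n_obs)


def _seasonal(doy, amplitude, phase_doy):
    return amplitude * np.sin(2 * np.pi * (doy - phase_doy) / 365.25)


def _ar1(rng, n, phi=0.7, sd=1.0):
    e = rng.standard_normal(n) * sd * np.sqrt(1 - phi**2)
    x = np.empty(n)
    x[0] = rng.standard_normal() * sd
    for t in range(1, n):
        x[t] = phi * x[t - 1] + e[t]
    return x


def generate_weather(start_date, end_date, seed=0, temp_humidity_corr=0.61) -> pd.DataFrame:
    """Daily weather series: smooth seasonality plus autocorrelated noise.

    Temperature (degC), humidity (Pa water vapour pressure), shortwave
    irradiance (W/m2) and precipitation (mm).  Humidity is driven by a
    mixture of the temperature process and an independent process so that
    the knob ``temp_humidity_corr`` sets their association (0 gives
    independent series); the default targets Spearman rho ~ 0.61.
    """
    dates = pd.date_range(start_date, end_date, freq="D")
    if len(dates) < 15:
        raise ValueError("date span must be at least 15 days (room for lag 2)")
    rng = _rng(seed, 2)
    doy = dates.dayofyear.to_numpy().astype(float)
    n = len(dates)

    # shared driver: temperature's standardized seasonal + AR(1) process
    z1_raw = _seasonal(doy, 1.0, 110.0) + _ar1(rng, n, phi=0.7, sd=0.45)
    z1 = (z1_raw - z1_raw.mean()) / z1_raw.std()
    z2_raw = _ar1(rng, n, phi=0.7, sd=1.0)
    z2 = (z2_raw - z2_raw.mean()) / z2_raw.std()
    c = float(temp_humidity_corr)
    hdrv = c * z1 + np.sqrt(max(0.0, 1 - c**2)) * z2

    temperature = 23.0 + 8.0 * z1
    humidity = 2000.0 + 500.0 * hdrv
    irradiance = 200.0 + 80.0 * (
        _seasonal(doy, 1.0, 80.0) + _ar1(rng, n, phi=0.5, sd=0.35)
    )
    wet = rng.random(n) < 0.30
    precipitation = np.where(wet, rng.gamma(shape=0.9, scale=8.0, size=n), 0.0)
    return pd.DataFrame(
        {
            "date": dates,
            "temperature": temperature,
            "humidity": humidity,
            "irradiance": irradiance,
            "precipitation": precipitation,
        }
    )


def draw_spatial_field(layout: SiteLayout, range_km, sd, rng) -> np.ndarray:
    """One Matérn(nu=1) Gaussian-field draw over the sites."""
    if sd == 0:
        return np.zeros(len(layout))
    cov = matern_covariance(layout.distances(), range_km, sd)
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal(len(layout))


def simulate_counts(
    layout: SiteLayout,
    design: pd.DataFrame,
    config: GeneratorConfig,
    site_index: Optional[np.ndarray] = None,
    field: Optional[np.ndarray] = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw a long trap-observation table from the generating model.

    ``design`` must contain ``site_id`` and ``date`` columns plus one column
    per key of ``config.true_beta``.  One spatial field is drawn per dataset
    (site-level, constant over time) unless ``field`` is supplied.

    Returns ``(obs, field)`` where ``obs`` has columns site_id, date, count.
    """
    rng = _rng(config.seed, 3)
    if site_index is None:
        id_to_idx = {s: i for i, s in enumerate(layout.site_id)}
        site_index = design["site_id"].map(id_to_idx).to_numpy()
    if field is None:
        field = draw_spatial_field(layout, config.true_range_km, config.true_sd, rng)

    missing = [k for k in config.true_beta if k not in design.columns]
    if missing:
        raise KeyError(f"design lacks generating columns: {missing}")
    X = design[list(config.true_beta)].to_numpy(float)
    beta = np.array(list(config.true_beta.values()), float)
    eta = config.intercept + X @ beta + field[site_index]
    bad = ~np.isfinite(eta)
    if np.any(bad):
        raise ValueError(f"non-finite linear predictor at design row {int(np.argmax(bad))}")
    mu = np.exp(eta)

    from .likelihoods import sample_counts

    y = sample_counts(rng, mu, config.family, nb_size=config.nb_size, zip_prob=config.zip_prob)
    obs = pd.DataFrame(
        {"site_id": design["site_id"].to_numpy(), "date": design["date"].to_numpy(), "count": y}
    )
    return obs, field


@dataclass
class ScenarioData:
    """One simulated study: layout, observations, design, and the truth."""

    layout: SiteLayout
    obs: pd.DataFrame  # site_id, date, count
    design: pd.DataFrame  # standardized model columns, rows aligned with obs
    weather: pd.DataFrame
    field: np.ndarray
    config: GeneratorConfig

    @property
    def y(self):
        return self.obs["count"].to_numpy()

    @property
    def site_index(self):
        id_to_idx = {s: i for i, s in enumerate(self.layout.site_id)}
        return self.obs["site_id"].map(id_to_idx).to_numpy()

    @property
    def truth(self):
        out = {"intercept": self.config.intercept}
        out.update(self.config.true_beta)
        return out


def build_scenario(config: GeneratorConfig) -> ScenarioData:
    """Draw a full study dataset under ``config``.

    Site-level covariates (every ``true_beta`` key that is neither a weather
    lag column nor an interaction) are standard normal per site; the columns
    ``impervious`` and ``grass``, when both present, are generated with a
    negative association (~ -0.67) because paving and lawn are zero-sum land
    covers.  Weather lag columns are built from one shared daily series.
    All parent columns are standardized over the fitting rows; interaction
    columns are products of standardized parents.
    """
    rng = _rng(config.seed, 4)
    layout = generate_sites(
        config.n_sites, config.extent_km, config.obs_mean, config.obs_min, seed=config.seed
    )
    pad_start = pd.Timestamp(config.start_date) - pd.Timedelta(days=14)
    weather = generate_weather(
        pad_start, config.end_date, seed=config.seed, temp_humidity_corr=config.temp_humidity_corr
    )
    all_dates = pd.date_range(config.start_date, config.end_date, freq="D")

    rows_site, rows_date = [], []
    for i in range(len(layout)):
        k = min(int(layout.n_obs[i]), len(all_dates))
        picked = np.sort(rng.choice(len(all_dates), size=k, replace=False))
        rows_site.append(np.full(k, i))
        rows_date.append(all_dates[picked])
    site_index = np.concatenate(rows_site)
    obs_dates = pd.DatetimeIndex(np.concatenate([d.to_numpy() for d in rows_date]))

    interactions = [k for k in config.true_beta if preprocess_is_interaction(k)]
    parents = [k for k in config.true_beta if not preprocess_is_interaction(k)]
    weather_cols = [k for k in parents if _weather_base(k) is not None]
    site_cols = [k for k in parents if _weather_base(k) is None]

    design = pd.DataFrame({"site_id": layout.site_id[site_index], "date": obs_dates})

    # site-level covariates, constant within site
    site_values = {}
    for col in site_cols:
        site_values[col] = rng.standard_normal(len(layout))
    if "impervious" in site_values and "grass" in site_values:
        r = -0.67
        site_values["grass"] = r * site_values["impervious"] + np.sqrt(1 - r**2) * site_values[
            "grass"
        ]
    for col in site_cols:
        design[col] = standardize(site_values[col][site_index])[0]

    # weather lag columns from the shared daily series
    for col in weather_cols:
        base, lag = _weather_base(col)
        series = weather.set_index("date")[base]
        lagged = build_lags(series, obs_dates, lags=(lag,), name=base)
        design[col] = standardize(lagged[f"{base}_lag{lag}"].to_numpy())[0]

    for col in interactions:
        a, b = col.split(" x ")
        design = add_interaction(design, a, b)

    obs, fld = simulate_counts(layout, design, config, site_index=site_index)
    model_cols = list(config.true_beta)
    return ScenarioData(layout, obs, design[["site_id", "date"] + model_cols], weather, fld, config)


def preprocess_is_interaction(name: str) -> bool:
    return " x " in name


def _weather_base(name: str):
    for base in WEATHER_VARS:
        for lag in (0, 1, 2):
            if name == f"{base}_lag{lag}":
                return base, lag
    return None


def config_from_file(path) -> GeneratorConfig:
    """Load a :class:`GeneratorConfig` from a YAML or JSON mapping."""
    import json

    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) if str(path).endswith((".yml", ".yaml")) else json.load(fh)
    known = set(GeneratorConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown generator config key(s): {sorted(unknown)}")
    return GeneratorConfig(**raw)


def aegypti_scenario(seed=0, n_sites=51, obs_mean=100.0, **overrides) -> ScenarioData:
    """Abundant-species study conditions (published coefficients as truth)."""
    cfg = GeneratorConfig(
        n_sites=n_sites,
        obs_mean=obs_mean,
        intercept=AEGYPTI_TRUTH["intercept"],
        true_beta={k: v for k, v in AEGYPTI_TRUTH.items() if k != "intercept"},
        true_range_km=AEGYPTI_RANGE_KM,
        nb_size=AEGYPTI_NB_SIZE,
        seed=seed,
        **overrides,
    )
    return build_scenario(cfg)


def albopictus_scenario(seed=0, n_sites=51, obs_mean=100.0, **overrides) -> ScenarioData:
    """Rare-species study conditions: low intercept, high zero fraction."""
    cfg = GeneratorConfig(
        n_sites=n_sites,
        obs_mean=obs_mean,
        intercept=ALBOPICTUS_TRUTH["intercept"],
        true_beta={k: v for k, v in ALBOPICTUS_TRUTH.items() if k != "intercept"},
        true_range_km=ALBOPICTUS_RANGE_KM,
        nb_size=ALBOPICTUS_NB_SIZE,
        seed=seed,
        **overrides,
    )
    return build_scenario(cfg)
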