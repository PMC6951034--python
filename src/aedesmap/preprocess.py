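"""Design-matrix construction: standardization, weather lags, interactions.

Covariates enter the models centered and scaled (subtract the mean, divide
by the sample standard deviation), so a coefficient is a log incidence rate
ratio per one-SD increase and zero represents the mean.  Weather enters as
the single daily value on the observation date (lag 0), 7 days earlier
(lag 1), or 14 days earlier (lag 2) — not a weekly mean.  Interaction
columns are elementwise products of the standardized parents and are *not*
re-standardized, preserving the usual scaled-interaction reading.

Standardization constants are computed on the fitting data and frozen: any
prediction-time covariate (e.g. gridded weather) must be transformed with
:func:`standardize_with` using the stored :class:`DesignInfo`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

INTERACTION_SEP = " x "


def standardize(x):
    """Center and scale a numeric vector.

    Returns ``(z, mean, sd)`` with ``z = (x - mean) / sd`` and sd the sample
    standard deviation (ddof=1).  Raises on constant input.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("standardize expects a 1-D vector of length >= 2")
    if np.any(~np.isfinite(x)):
        raise ValueError("non-finite value in column")
    mean = x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: cannot standardize a constant column")
    return (x - mean) / sd, float(mean), float(sd)


def destandardize(z, mean, sd):
    """Inverse of :func:`standardize` given the stored constants."""
    return np.asarray(z, dtype=np.float64) * sd + mean


def standardize_with(x, mean, sd):
    """Apply frozen training constants to new (prediction-time) values."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    return (np.asarray(x, dtype=np.float64) - mean) / sd


def build_lags(series: pd.Series, obs_dates, lags=(0, 1, 2), name=None):
    """Lagged daily-value columns for a set of observation dates.

    ``series`` is a daily series indexed by date; lag k (in weeks) holds the
    single daily value 7*k days before each observation date.

    Returns a DataFrame with one column per lag named ``{name}_lag{k}``.
    """
    if not isinstance(series, pd.Series):
        raise TypeError("series must be a pandas Series indexed by date")
    name = name or series.name or "value"
    idx = pd.DatetimeIndex(series.index)
    obs = pd.DatetimeIndex(pd.to_datetime(obs_dates))
    out = {}
    for k in lags:
        shifted = obs - pd.Timedelta(days=7 * int(k))
        missing = shifted.difference(idx)
        if len(missing):
            raise ValueError(
                f"series does not cover lag-{k} date(s), e.g. "
                f"{missing[0].date().isoformat()}"
            )
        out[f"{name}_lag{k}"] = series.reindex(shifted).to_numpy()
    return pd.DataFrame(out, index=pd.RangeIndex(len(obs)))


def flag_correlated_pairs(design: pd.DataFrame, threshold=0.5):
    """All unordered column pairs with |Spearman rho| above the threshold.

    Spearman correlations use average ranks for ties.  Returns a list of
    ``(col_a, col_b, rho)`` sorted by descending |rho|.
    """
    if len(design) < 3:
        raise ValueError("need at least 3 rows to estimate rank correlations")
    cols = list(design.columns)
    if len(cols) < 2:
        return []
    rho, _ = spearmanr(design.to_numpy())
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    pairs = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = float(rho[i, j])
            if abs(r) > threshold:
                pairs.append((cols[i], cols[j], r))
    pairs.sort(key=lambda t: -abs(t[2]))
    return pairs


def interaction_name(a: str, b: str) -> str:
    return f"{a}{INTERACTION_SEP}{b}"


def add_interaction(design: pd.DataFrame, a: str, b: str) -> pd.DataFrame:
    """Append the product column ``a x b`` of two (standardized) columns.

    The product is taken as-is — it is deliberately not re-standardized, so
    its mean need not be zero.  Raises if the interaction already exists.
    """
    for col in (a, b):
        if col not in design.columns:
            raise KeyError(f"column {col!r} not in design")
    name = interaction_name(a, b)
    alt = interaction_name(b, a)
    if name in design.columns or alt in design.columns:
        raise ValueError(f"interaction {name!r} already present")
    out = design.copy()
    out[name] = design[a].to_numpy() * design[b].to_numpy()
    return out


@dataclass
class DesignInfo:
    """Frozen per-column standardization constants and lag tags."""

    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)
    lag_tags: dict = field(default_factory=dict)  # column -> "lag0"|"lag1"|"lag2"

    def transform(self, name: str, values):
        return standardize_with(values, self.means[name], self.sds[name])

    def inverse(self, name: str, values):
        return destandardize(values, self.means[name], self.sds[name])


def build_design(raw: pd.DataFrame, columns=None) -> tuple[pd.DataFrame, DesignInfo]:
    """Standardize the given columns of a raw covariate table.

    Returns the standardized design plus the :class:`DesignInfo` holding the
    frozen constants; columns named like ``temperature_lag1`` get lag tags.
    """
    columns = list(columns or raw.columns)
    info = DesignInfo()
    out = {}
    for col in columns:
        z, mean, sd = standardize(raw[col].to_numpy())
        out[col] = z
        info.means[col] = mean
        info.sds[col] = sd
        for tag in ("lag0", "lag1", "lag2"):
            if col.endswith(f"_{tag}"):
                info.lag_tags[col] = tag
    return pd.DataFrame(out, index=raw.index), info


def save_design(design: pd.DataFrame, info: DesignInfo, csv_path):
    """Write the design CSV plus a JSON sidecar with the frozen constants."""
    csv_path = Path(csv_path)
    design.to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {"means": info.means, "sds": info.sds, "lag_tags": info.lag_tags},
            indent=2,
        )
    )
    return csv_path, sidecar


def load_design(csv_path):
    csv_path = Path(csv_path)
    design = pd.read_csv(csv_path)
    sidecar = csv_path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    info = DesignInfo(means=meta["means"], sds=meta["sds"], lag_tags=meta["lag_tags"])
    return design, info
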