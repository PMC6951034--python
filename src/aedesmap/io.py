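"""Readers, writers, and validated configuration for the pipeline.

Trap observations travel as long-format CSV (site_id, easting_km,
northing_km, date, species, count); coordinates are projected planar km
(UTM-style) — no latitude/longitude arithmetic happens inside the models.
Configuration is YAML validated by a pydantic schema that rejects unknown
keys.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

logger = logging.getLogger(__name__)

TRAP_COLUMNS = ["site_id", "easting_km", "northing_km", "date", "species", "count"]


def read_trap_table(path) -> pd.DataFrame:
    """Read and validate a long-format trap-observation CSV.

    Counts must be non-negative integers and dates ISO-8601; errors name
    the offending row (1-based, excluding the header).  Duplicate
    (site, date, species) rows are allowed — multiple trap-nights — with a
    logged warning.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trap table missing column(s): {missing}")
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = counts.isna() | (counts < 0) | (counts != counts.round())
    if bad.any():
        row = int(bad.idxmax()) + 1
        raise ValueError(f"negative or non-integer count at row {row}")
    df["count"] = counts.astype(int)
    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError):
        parsed = pd.to_datetime(df["date"], errors="coerce")
        row = int(parsed.isna().idxmax()) + 1
        raise ValueError(f"malformed date at row {row}")
    dups = df.duplicated(subset=["site_id", "date", "species"], keep=False)
    if dups.any():
        logger.warning("%d duplicate (site, date, species) rows kept (multiple trap-nights)", int(dups.sum()))
    return df


def write_trap_table(df: pd.DataFrame, path):
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
    return Path(path)


def filter_sparse_sites(table: pd.DataFrame, min_obs=30):
    """Drop sites with fewer than ``min_obs`` rows (strictly fewer).

    Returns ``(filtered, report)`` where the report lists dropped sites and
    retained totals.  Raises if nothing survives.
    """
    counts = table.groupby("site_id").size()
    keep = counts[counts >= min_obs].index
    dropped = sorted(set(counts.index) - set(keep))
    filtered = table[table["site_id"].isin(keep)].reset_index(drop=True)
    if filtered.empty:
        raise ValueError(f"all sites have fewer than {min_obs} observations")
    report = {
        "min_obs": int(min_obs),
        "n_sites_in": int(len(counts)),
        "n_sites_kept": int(len(keep)),
        "dropped_sites": [str(s) for s in dropped],
        "n_obs_kept": int(len(filtered)),
    }
    return filtered, report


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------- config


class GeneratorSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    scenario: str = "aegypti"  # aegypti | albopictus
    n_sites: int = 51
    obs_mean: float = 100.0
    extent_km: float = 10.0


class SelectionSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = False
    n_iter: int = 3000
    burn_in: int = 1000
    top_k: int = 12


class PriorSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    range_ref: float = 10.0
    range_prob: float = 0.95
    sd_ref: float = 0.5
    sd_prob: float = 0.05
    beta_sd: float = 10.0


class MCMCSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    chains: int = 2
    draws: int = 1000
    warmup: int = 1000
    rhat_action: str = "raise"


class GridSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    spacing_km: float = 1.0
    n_prediction_draws: int = 200


class PipelineConfig(BaseModel):
    """Schema-validated end-to-end pipeline configuration."""

    model_config = ConfigDict(extra="forbid")
    output_dir: str = "pipeline_output"
    seed: int = 0
    family: str = "negbin"
    spatial: bool = True
    n_posterior_sims: int = 500
    generator: GeneratorSettings = Field(default_factory=GeneratorSettings)
    selection: SelectionSettings = Field(default_factory=SelectionSettings)
    priors: PriorSettings = Field(default_factory=PriorSettings)
    mcmc: MCMCSettings = Field(default_factory=MCMCSettings)
    grid: GridSettings = Field(default_factory=GridSettings)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def save_config(config: PipelineConfig, path):
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)
    return Path(path)


def write_json(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)
    return Path(path)
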