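"""End-to-end driver: simulate -> preprocess -> select -> fit -> validate -> predict.

Each stage writes its artifacts under the configured output directory and
the run ends with a provenance manifest (config echo, seeds, file hashes).
Reruns with the same config are deterministic.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as aio
from .model import ModelPriors, SpatialCountModel
from .prediction import make_grid, weekly_weather_design
from .selection import choose_top_six, spike_slab_select
from .spatial import PCPriorSpec
from .synthetic import WEATHER_VARS, aegypti_scenario, albopictus_scenario

logger = logging.getLogger(__name__)


def run_pipeline(config: aio.PipelineConfig, output_dir=None):
    """Execute the full analysis on one synthetic scenario.

    Returns a dict of in-memory artifacts; files land in ``output_dir``.
    Raises at the failing stage with the stage name; artifacts written by
    earlier stages are kept.
    """
    outdir = Path(output_dir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config.model_dump(), "stages": {}, "files": {}}
    artifacts = {}

    def _stage(name):
        logger.info("stage %s (seed=%d)", name, config.seed)
        manifest["stages"][name] = {"seed": config.seed, "started": time.time()}

    def _fail(name, err):
        raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err

    # ---------------------------------------------------------- simulate
    _stage("simulate")
    try:
        scenario_fn = {"aegypti": aegypti_scenario, "albopictus": albopictus_scenario}[
            config.generator.scenario
        ]
        data = scenario_fn(
            seed=config.seed,
            n_sites=config.generator.n_sites,
            obs_mean=config.generator.obs_mean,
            extent_km=config.generator.extent_km,
        )
    except Exception as err:
        _fail("simulate", err)
    obs = data.obs.assign(
        species=config.generator.scenario,
        easting_km=data.layout.easting[data.site_index],
        northing_km=data.layout.northing[data.site_index],
    )[["site_id", "easting_km", "northing_km", "date", "species", "count"]]
    aio.write_trap_table(obs, outdir / "trap_observations.csv")
    data.design.to_csv(outdir / "design.csv", index=False)
    data.weather.to_csv(outdir / "weather.csv", index=False)
    artifacts["data"] = data

    # ---------------------------------------------------------- preprocess
    _stage("preprocess")
    try:
        filtered, report = aio.filter_sparse_sites(obs, min_obs=0)
        aio.write_json(report, outdir / "site_filter_report.json")
        terms = [c for c in data.design.columns if c not in ("site_id", "date")]
        design = data.design[terms]
    except Exception as err:
        _fail("preprocess", err)

    # ---------------------------------------------------------- select
    chosen = terms
    if config.selection.enabled:
        _stage("select")
        try:
            parents = [t for t in terms if " x " not in t]
            sel = spike_slab_select(
                data.y,
                design[parents],
                n_iter=config.selection.n_iter,
                burn_in=config.selection.burn_in,
                seed=config.seed,
            )
            groups = {
                base: [f"{base}_lag{k}" for k in (0, 1, 2)] for base in WEATHER_VARS
            }
            chosen_parents = choose_top_six(sel, groups, top_k=config.selection.top_k)
            chosen = chosen_parents + [
                t for t in terms if " x " in t and all(p in chosen_parents for p in t.split(" x "))
            ]
            sel.table.to_csv(outdir / "selection_report.csv")
            aio.write_json({"chosen": chosen}, outdir / "selection_chosen.json")
            artifacts["selection"] = sel
        except Exception as err:
            _fail("select", err)

    # ---------------------------------------------------------- fit
    _stage("fit")
    try:
        priors = ModelPriors(
            beta_sd=config.priors.beta_sd,
            pc=PCPriorSpec(
                config.priors.range_ref,
                config.priors.range_prob,
                config.priors.sd_ref,
                config.priors.sd_prob,
            ),
        )
        model = SpatialCountModel(
            data.y,
            design[chosen],
            site_index=data.site_index,
            coords=np.column_stack([data.layout.easting, data.layout.northing]),
            family=config.family,
            spatial=config.spatial,
            priors=priors,
        )
        res = model.fit(
            draws=config.mcmc.draws,
            warmup=config.mcmc.warmup,
            chains=config.mcmc.chains,
            seed=config.seed,
            rhat_action=config.mcmc.rhat_action,
        )
    except Exception as err:
        _fail("fit", err)
    artifacts["results"] = res
    (outdir / "summary.txt").write_text(res.summary() + "\n")
    dic, pd_eff = res.dic()
    od, od_ci = res.overdispersion()
    post = res.params.to_frame("mean").join(res.conf_int())
    post.to_csv(outdir / "posterior_coefficients.csv")
    res.hyper_summary().to_csv(outdir / "posterior_hyperparameters.csv")
    aio.write_json(
        {
            "DIC": dic,
            "pD": pd_eff,
            "overdispersion": od,
            "overdispersion_CI": od_ci,
            "rhat": {k: v["rhat"] for k, v in res.diagnostics.items()},
        },
        outdir / "fit_report.json",
    )

    # ---------------------------------------------------------- validate
    _stage("validate")
    try:
        ens = res.posterior_predictive(n_sims=config.n_posterior_sims, seed=config.seed)
        check = res.scaled_residuals(ensemble=ens)
        band = pd.DataFrame(
            {
                "count": ens.count_values,
                "observed": ens.observed_freq,
                "lower": ens.band_lower,
                "upper": ens.band_upper,
            }
        )
        band.to_csv(outdir / "predictive_band.csv", index=False)
        aio.write_json(
            {
                "band_coverage": ens.band_coverage(),
                "zero_band_position": ens.zero_band_position(),
                "residual_fraction_outside": check.fraction_outside,
                "residual_mean_shift": check.mean_shift,
            },
            outdir / "validation_report.json",
        )
        try:
            import matplotlib

            matplotlib.use("Agg")
            from .validation import plot_predictive_check, plot_residual_envelope

            ax = plot_predictive_check(ens)
            ax.figure.savefig(outdir / "predictive_check.png", dpi=120)
            ax = plot_residual_envelope(check)
            ax.figure.savefig(outdir / "residual_envelope.png", dpi=120)
        except Exception as plot_err:  # plotting must never sink the run
            logger.warning("figure rendering skipped: %s", plot_err)
    except Exception as err:
        _fail("validate", err)
    artifacts["ensemble"] = ens

    # ---------------------------------------------------------- predict
    _stage("predict")
    try:
        grid = make_grid(config.generator.extent_km, config.grid.spacing_km)
        week_design = weekly_weather_design(
            data.weather, [t for t in chosen], data_info_for(data, chosen)
        )
        surface = res.predict_weekly(
            grid, week_design, n_draws=config.grid.n_prediction_draws, seed=config.seed
        )
        surface.table.to_csv(outdir / "weekly_grid_predictions.csv", index=False)
        surface.field.to_csv(outdir / "interpolated_field.csv", index=False)
        series = surface.weekly_series("sum")
        series.to_csv(outdir / "weekly_series.csv", index=False)
        peak = surface.peak_week("sum")
        surface.to_geojson(peak, outdir / "peak_week_map.geojson")
        aio.write_json({"peak_week": peak}, outdir / "prediction_report.json")
    except Exception as err:
        _fail("predict", err)
    artifacts["surface"] = surface

    # ---------------------------------------------------------- manifest
    for f in sorted(outdir.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["files"][f.name] = aio.sha256_of(f)
    aio.write_json(manifest, outdir / "manifest.json")
    artifacts["manifest"] = manifest
    return artifacts


def data_info_for(data, terms):
    """DesignInfo for weekly prediction: recompute the frozen constants of
    the weather parents from the fitting rows (generator columns are already
    standardized, so means/sds reconstruct from the raw daily series)."""
    from .preprocess import DesignInfo, build_lags

    info = DesignInfo()
    daily = data.weather.set_index("date")
    obs_dates = pd.DatetimeIndex(data.design["date"])
    for term in terms:
        if " x " in term:
            continue
        for base in WEATHER_VARS:
            for lag in (0, 1, 2):
                if term == f"{base}_lag{lag}":
                    vals = build_lags(daily[base], obs_dates, lags=(lag,), name=base)[
                        f"{base}_lag{lag}"
                    ].to_numpy()
                    info.means[term] = float(vals.mean())
                    info.sds[term] = float(vals.std(ddof=1))
                    info.lag_tags[term] = f"lag{lag}"
    return info
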