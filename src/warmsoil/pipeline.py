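"""Configurable end-to-end pipeline: simulate -> flux -> response -> stocks -> c14.

Stages communicate through a results bundle (a dict of DataFrames); every
run writes tidy CSVs plus a manifest that fully determines a re-run (config
snapshot, seed, file digests, package version).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from warmsoil import __version__, flux, radiocarbon, response, stocks, synthetic
from warmsoil.tables import RunManifest, file_digest, write_table

ALL_STAGES = ("simulate", "flux", "response", "stocks", "c14")


def _synthetic_config(config: dict) -> synthetic.SyntheticConfig:
    syn = dict(config.get("synthetic", {}))
    years = syn.pop("years", (2005, 2022))
    return synthetic.SyntheticConfig(
        seed=int(config.get("seed", 0)), years=tuple(years), **syn
    )


def build_response_records(
    campaign: pd.DataFrame, pairs: list[response.PlotPair]
) -> pd.DataFrame:
    """Block-date paired records (fluxes and temperatures) from a campaign."""
    work = flux.compute_campaign_fluxes(campaign)
    means = flux.plot_date_means(work)
    rows = []
    for p in pairs:
        ctrl = means[means["plot_id"] == p.control_plot_id].set_index("date")
        warm = means[means["plot_id"] == p.warmed_plot_id].set_index("date")
        common = ctrl.index.intersection(warm.index)
        for date in common:
            rows.append(
                (
                    p.block_id,
                    date,
                    ctrl.at[date, "flux_umol_m2_s"],
                    warm.at[date, "flux_umol_m2_s"],
                    ctrl.at[date, "soil_temp_5cm_c"],
                    warm.at[date, "soil_temp_5cm_c"],
                )
            )
    return pd.DataFrame(
        rows,
        columns=["block_id", "date", "r_control", "r_warming", "t_control", "t_warming"],
    )


def run_pipeline(config: dict) -> tuple[dict[str, pd.DataFrame], dict]:
    """Execute the configured stages; return (bundle, extras).

    ``config`` keys: seed, stages (subset of simulate/flux/response/stocks/
    c14; later stages require the earlier ones), synthetic (SyntheticConfig
    overrides), budget (autotrophic_fraction, stock_year), c14 (combos,
    noise_sigma, n_starts). ``extras`` carries scalar results (surplus
    efflux, budget closure, fitted ages) keyed by stage.
    """
    stages = list(config.get("stages", ALL_STAGES))
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    for i, stage in enumerate(stages):
        if ALL_STAGES.index(stage) != i:
            missing = [s for s in ALL_STAGES[: ALL_STAGES.index(stage)] if s not in stages]
            if missing:
                raise ValueError(f"stage {stage!r} requires earlier stages {missing}")
    syncfg = _synthetic_config(config)
    pairs = synthetic.plot_pairs(syncfg)
    bundle: dict[str, pd.DataFrame] = {}
    extras: dict[str, dict] = {}

    if "simulate" in stages:
        climate = synthetic.synth_soil_climate(syncfg)
        campaign = synthetic.synth_flux_campaign(syncfg, climate)
        inventory = synthetic.synth_soc_inventory(syncfg)
        curve = synthetic.synth_atmospheric_curve()
        bundle["climate"] = climate.rename(columns={"date": "timestamp"})
        bundle["campaign"] = campaign
        bundle["inventory"] = inventory
        bundle["atmospheric_curve"] = pd.DataFrame(
            {"year": curve.years, "delta14c_permil": curve.delta14c}
        )

    if "flux" in stages:
        temp_log = bundle["climate"]
        campaign = flux.compute_campaign_fluxes(bundle["campaign"])
        years = range(syncfg.years[0], syncfg.years[1] + 1)
        bundle["annual_budgets"] = flux.annual_budgets(
            campaign, temp_log, years, study_years=syncfg.years
        )

    if "response" in stages:
        records = build_response_records(bundle["campaign"], pairs)
        retained = response.filter_valid_pairs(records, pairs)
        bundle["response_records"] = retained
        bundle["annual_response"] = response.annual_response_series(retained)
        mean_s, se_s, per_block = response.surplus_efflux(
            bundle["annual_budgets"],
            pairs,
            range(syncfg.years[0], syncfg.years[1] + 1),
            method="interpolation",
        )
        extras["response"] = {
            "surplus_kg_c_m2_mean": mean_s,
            "surplus_kg_c_m2_se": se_s,
            "surplus_per_block": per_block.to_dict(),
        }

    if "stocks" in stages:
        layer = stocks.plot_layer_stocks(bundle["inventory"])
        corrected = stocks.paired_corrected_stocks(layer, pairs)
        bundle["layer_stocks"] = layer
        bundle["corrected_stocks"] = corrected
        budget_cfg = dict(config.get("budget", {}))
        stock_year = int(budget_cfg.get("stock_year", syncfg.years[0] + 14))
        autotrophic = float(budget_cfg.get("autotrophic_fraction", 0.40))
        mean_s, _, _ = response.surplus_efflux(
            bundle["annual_budgets"],
            pairs,
            range(syncfg.years[0], stock_year),
            method="interpolation",
        )
        totals = corrected[corrected["layer"] == "0-20 total"]
        delta_soc = float(
            (
                totals["warmed_stock_corrected_kg_c_m2"]
                - totals["control_stock_kg_c_m2"]
            ).mean()
        )
        closure = stocks.closed_budget(
            mean_s, autotrophic, delta_soc, stock_year - syncfg.years[0]
        )
        extras["stocks"] = {
            "surplus_to_stock_year_kg_c_m2": closure.surplus_cum,
            "delta_soc_kg_c_m2": closure.delta_soc,
            "heterotrophic_cum_kg_c_m2": closure.heterotrophic_cum,
            "missing_input_kg_c_m2": closure.missing_input,
            "missing_input_annual_kg_c_m2_yr": closure.missing_input_annual,
        }

    if "c14" in stages:
        c14cfg = dict(config.get("c14", {}))
        combos = [tuple(c) for c in c14cfg.get("combos", [("control", "0-10")])]
        noise = float(c14cfg.get("noise_sigma", syncfg.c14_noise_sigma))
        n_starts = int(c14cfg.get("n_starts", 3))
        curve = synthetic.synth_atmospheric_curve()
        rng = syncfg.rng("radiocarbon")
        fit_rows, age_rows = [], []
        for treatment, depth in combos:
            model = synthetic.default_radiocarbon_model(treatment, depth)
            obs = synthetic.synth_radiocarbon_obs(
                model, curve, noise_sigma=noise, seed=int(rng.integers(2**31 - 1))
            )
            fit = radiocarbon.fit_model(
                obs,
                curve,
                litter_input=synthetic.LITTERFALL_C_INPUT,
                n_starts=n_starts,
                seed=int(rng.integers(2**31 - 1)),
                depth=depth,
                treatment=treatment,
            )
            sys_age = radiocarbon.age_distribution(fit.model, "system")
            soc_age = radiocarbon.age_distribution(fit.model, "bulk_soc")
            transit = radiocarbon.transit_time_distribution(fit.model)
            fit_rows.append(
                (treatment, depth, *[fit.params[k] for k in ("k1", "k2", "k3", "a31", "a32")], fit.chisqr)
            )
            age_rows.append(
                (
                    treatment,
                    depth,
                    sys_age.mean,
                    sys_age.median,
                    soc_age.mean,
                    soc_age.median,
                    transit.mean,
                    transit.median,
                )
            )
        bundle["c14_fits"] = pd.DataFrame(
            fit_rows,
            columns=["treatment", "depth", "k1", "k2", "k3", "a31", "a32", "chisqr"],
        )
        bundle["c14_ages"] = pd.DataFrame(
            age_rows,
            columns=[
                "treatment",
                "depth",
                "system_mean_age_yr",
                "system_median_age_yr",
                "soc_mean_age_yr",
                "soc_median_age_yr",
                "mean_transit_yr",
                "median_transit_yr",
            ],
        )
        extras["c14"] = {"combos": [list(c) for c in combos]}

    return bundle, extras


def write_results(
    bundle: dict[str, pd.DataFrame],
    out_dir: str | Path,
    config: dict,
    extras: dict | None = None,
) -> RunManifest:
    """Write one tidy CSV per bundle table plus the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=_jsonable(config),
        seed=int(config.get("seed", 0)),
        package_version=__version__,
    )
    for name, df in bundle.items():
        path = write_table(df, out / f"{name}.csv")
        manifest.output_digests[f"{name}.csv"] = file_digest(path)
    if extras:
        import json

        extras_path = out / "summary.json"
        extras_path.write_text(json.dumps(_jsonable(extras), indent=2, sort_keys=True) + "\n")
        manifest.output_digests["summary.json"] = file_digest(extras_path)
    manifest.write(out / "manifest.json")
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
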