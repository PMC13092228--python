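"""One-command orchestration of the full analysis, with a run manifest.

Stages: ingest (load, harmonize, filter, pool) -> coverage-standardized
diversity series -> SST covariates -> trend and attribution models ->
evidence report -> log-response-ratio / range-class analysis.  Every stage
logs record and taxon counts to the manifest so filter behaviour is
auditable, and a fixed seed makes the whole run reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evidence, inference, population_change, survey_data, synthetic_data, temperature
from .diversity import diversity_time_series

__all__ = ["run_analysis", "simulate_inputs", "DEFAULT_CONFIG"]

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 1931,
    "metric_for_attribution": "q1",
    "n_boot": 200,
    "min_individuals": 20,
    "min_plots": 5,
    "mcmc": {},          # overrides for inference.McmcConfig
    "sim": {},           # overrides for synthetic_data.SimConfig
}


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def simulate_inputs(out_dir: Path, config: dict | None = None) -> dict[str, Path]:
    """Write a simulated raw database (records, crosswalk, traits, SST, truth)."""
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim_cfg = synthetic_data.SimConfig(**cfg["sim"])
    records, truth = synthetic_data.generate_community(sim_cfg, seed=cfg["seed"])
    sst = synthetic_data.generate_temperature(sim_cfg, seed=cfg["seed"] + 1)
    paths = {
        "records": out_dir / "records.csv",
        "crosswalk": out_dir / "crosswalk.csv",
        "traits": out_dir / "traits.csv",
        "sst": out_dir / "sst.csv",
        "truth": out_dir / "truth.json",
    }
    records.to_csv(paths["records"], index=False)
    truth.crosswalk.to_csv(paths["crosswalk"], index=False)
    truth.traits.to_csv(paths["traits"], index=False)
    sst.to_csv(paths["sst"], index=False)
    paths["truth"].write_text(
        json.dumps(
            {
                "beta_temp_true": truth.beta_temp_true,
                "era_effort": truth.era_effort,
                "quirk_counts": truth.quirk_counts,
                "true_total_counts": truth.true_total_counts,
                "observed_total_counts": truth.observed_total_counts,
            },
            indent=2,
        )
    )
    return paths


def run_analysis(
    records_path,
    crosswalk_path,
    traits_path,
    sst_path,
    out_dir,
    config: dict | None = None,
) -> dict:
    """Execute ingest -> diversity -> temperature -> models -> evidence -> LRR.

    Returns the run manifest (also written to ``out_dir/manifest.json``).
    Stage failures propagate after the manifest records completed stages.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = {
        "records": Path(records_path),
        "crosswalk": Path(crosswalk_path),
        "traits": Path(traits_path),
        "sst": Path(sst_path),
    }
    for name, p in inputs.items():
        if not p.exists():
            raise FileNotFoundError(f"stage ingest: missing {name} file {p}")
    manifest: dict = {
        "config": cfg,
        "config_hash": hashlib.sha256(
            yaml.safe_dump(cfg, sort_keys=True).encode()
        ).hexdigest()[:16],
        "inputs": {k: _digest(p) for k, p in inputs.items()},
        "stages": [],
    }

    def stage(name: str, **counts) -> None:
        manifest["stages"].append({"stage": name, **counts})
        log.info("stage %s: %s", name, counts)

    try:
        crosswalk = pd.read_csv(inputs["crosswalk"])
        records = survey_data.load_raw_records(inputs["records"])
        stage("load", n_records=len(records))

        records, name_report = survey_data.harmonize_taxonomy(records, crosswalk)
        stage("harmonize", n_records=len(records), n_names_changed=len(name_report))

        filtered, filter_report = survey_data.apply_quantitative_filters(records, crosswalk)
        stage("filter", n_records=len(filtered),
              n_removed=filter_report.total_records_removed)
        (out / "filter_report.json").write_text(json.dumps(filter_report.to_dict(), indent=2))

        mobility = crosswalk.drop_duplicates("analysis_taxon").set_index("analysis_taxon")["mobility"]
        matrix = survey_data.pool_site_year_matrix(filtered, group_mask=mobility)
        matrix.counts.to_csv(out / "site_year_matrix.csv")
        stage("pool", n_site_years=len(matrix.years), n_taxa=len(matrix.taxa),
              n_individuals=matrix.total())

        div = diversity_time_series(
            matrix, n_boot=cfg["n_boot"], seed=cfg["seed"],
        )
        div.to_csv(out / "diversity_series.csv", index=False)
        stage("diversity", n_estimates=len(div))

        sst = temperature.load_temperature_series(inputs["sst"])
        recent = [y for y in matrix.years if y != survey_data.BASELINE_ERA]
        survey_dates = {int(y): date(int(y), 6, 1) for y in recent}
        covs = temperature.covariates_for_surveys(sst, survey_dates)
        covs.to_csv(out / "sst_covariates.csv", index=False)
        stage("sst", n_years=int(covs["t_max_p90"].notna().sum()))

        metric = cfg["metric_for_attribution"]
        mseries = div[div["metric"] == metric].copy()
        baseline_value = float(
            mseries.loc[mseries["year"] == survey_data.BASELINE_ERA, "estimate"].iloc[0]
        )
        recent_rows = mseries[mseries["year"] != survey_data.BASELINE_ERA]
        tmap = dict(zip(covs["year"], covs["t_max_p90"]))
        tdf = pd.DataFrame(
            {
                "year": recent_rows["year"].astype(int),
                "era": [survey_data.era_of_year(int(y)) for y in recent_rows["year"]],
                "y": recent_rows["estimate"].to_numpy(),
                "t": [tmap.get(int(y), np.nan) for y in recent_rows["year"]],
            }
        ).dropna()
        trend_data = inference.TrendData.from_frame(tdf)

        mcmc = inference.McmcConfig(**{"seed": cfg["seed"], **cfg["mcmc"]})
        fit1 = inference.fit_trend_era_model(trend_data, mcmc=mcmc)
        fit2 = inference.fit_temp_linear_model(trend_data, mcmc=mcmc)
        fit_naive = inference.fit_temp_linear_model(trend_data, mcmc=mcmc, naive=True)
        gp_mcmc = inference.McmcConfig(
            **{**mcmc.__dict__, "n_iter": 2 * mcmc.n_iter, "n_warmup": 2 * mcmc.n_warmup}
        )
        fit3 = inference.fit_temp_gp_model(trend_data, mcmc=gp_mcmc, latent_draws=False)
        stage("fit", models=["trend_era", "temp_linear", "temp_naive", "temp_gp"],
              diagnostics_passed=[f.diagnostics_passed for f in (fit1, fit2, fit_naive, fit3)])

        pred = inference.posterior_predict(
            fit1, trend_data.year, force=not fit1.diagnostics_passed
        )
        pred.to_csv(out / "posterior_predictions.csv", index=False)
        envelope = evidence.baseline_envelope_test(pred, baseline_value)

        p_year = evidence.prob_of_sign(fit1.draws("beta_year"), "negative")
        report = {
            "metric": metric,
            "baseline_value": baseline_value,
            "trend": {
                "beta_year_median": float(np.median(fit1.draws("beta_year"))),
                "p_negative": p_year,
                "grade": evidence.classify_slope_evidence(p_year),
            },
            "baseline_envelope": {
                "grade": envelope["grade"],
                "n_containing": envelope["n_containing"],
                "change_after": envelope["change_after"],
            },
            "temperature": {},
        }
        for label, fit in (("naive", fit_naive), ("linear_adjusted", fit2), ("gp_adjusted", fit3)):
            p_neg = fit.extras["p_beta_temp_negative"]
            bt = fit.draws("beta_temp")
            report["temperature"][label] = {
                "beta_temp_median": float(np.median(bt)),
                "ci95": [float(v) for v in np.quantile(bt, [0.025, 0.975])],
                "p_negative": p_neg,
                "grade": evidence.classify_slope_evidence(p_neg),
            }
        stage("evidence", grade_trend=report["trend"]["grade"],
              grade_envelope=report["baseline_envelope"]["grade"])

        occupancy = survey_data.plot_occupancy(filtered)
        incl = population_change.apply_inclusion_filter(
            matrix, occupancy, cfg["min_individuals"], cfg["min_plots"]
        )
        lrr = population_change.compute_lrr(matrix, taxa=incl.retained)
        traits = pd.read_csv(inputs["traits"]).set_index("taxon")
        lrr["range_class"] = [
            population_change.assign_range_category(
                traits["northern_limit_lat"].get(t, np.nan),
                traits["southern_limit_lat"].get(t, np.nan),
            )
            for t in lrr["taxon"]
        ]
        lrr.to_csv(out / "lrr_table.csv", index=False)
        contrast = population_change.range_contrast_inputs(lrr)
        fit4 = inference.fit_lrr_range_model(
            inference.LRRData.from_frame(contrast[contrast["in_contrast"]]),
            mcmc=inference.McmcConfig(**{**inference.LRR_MCMC.__dict__, "seed": cfg["seed"]}),
        )
        delta = fit4.extras["delta_draws"]
        report["range_contrast"] = {
            "n_taxa": int(contrast["in_contrast"].sum()),
            "delta_median": float(np.median(delta)),
            "delta_ci95": [float(v) for v in fit4.extras["delta_ci95"]],
            "counts": evidence.count_strong_changes(lrr),
        }
        stage("lrr", n_retained=len(incl.retained),
              fraction_individuals=incl.fraction_individuals_retained)

        (out / "evidence_report.json").write_text(json.dumps(report, indent=2, default=str))
        manifest["completed"] = True
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
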