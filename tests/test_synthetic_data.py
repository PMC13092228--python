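import numpy as np
import pandas as pd
import pytest

from rockyshore import survey_data as sv
from rockyshore import synthetic_data as sd
from rockyshore.temperature import covariates_for_surveys

QUIET = dict(synonym_rate=0.0, qualitative_only_rate=0.0, genus_level_rate=0.0,
             above_genus_rate=0.0, include_epibiont=False)


def test_temperature_series_deterministic():
    cfg = sd.SimConfig()
    a = sd.generate_temperature(cfg, seed=4)
    b = sd.generate_temperature(cfg, seed=4)
    pd.testing.assert_frame_equal(a, b)
    c = sd.generate_temperature(cfg, seed=5)
    assert not a["sst_c"].equals(c["sst_c"])


def _annual_p90s(series, years):
    from datetime import date

    cov = covariates_for_surveys(series, {y: date(y, 6, 1) for y in years})
    return cov.set_index("year")["t_max_p90"]


def test_temperature_trend_controls_annual_p90():
    flat = sd.SimConfig(sst_trend_c_per_yr=0.0, sst_noise_sd=0.0)
    p90 = _annual_p90s(sd.generate_temperature(flat, seed=1), range(1995, 2020))
    assert p90.max() - p90.min() < 0.02  # leap-day jitter only
    warming = sd.SimConfig(sst_trend_c_per_yr=0.01, sst_noise_sd=0.0)
    p90w = _annual_p90s(sd.generate_temperature(warming, seed=1), [1993, 2023])
    assert p90w[2023] - p90w[1993] == pytest.approx(0.30, abs=0.03)


def test_community_deterministic_and_conserved():
    cfg = sd.SimConfig(**QUIET)
    r1, t1 = sd.generate_community(cfg, seed=9)
    r2, t2 = sd.generate_community(cfg, seed=9)
    pd.testing.assert_frame_equal(r1, r2)
    # bookkeeping identity: emitted counts equal the generator's own tally and
    # never exceed the pre-thinning totals
    assert r1["count"].sum() == t1.observed_total_counts
    assert t1.observed_total_counts <= t1.true_total_counts


def test_effort_thinning_is_coupled_monotone():
    base = sd.SimConfig(**QUIET)
    low_effort = {e: {"mobile": 1.0, "sessile": 1.0} for e in ["1931-1933", *sd.RECENT_YEARS]}
    low_effort["1999-2015"] = {"mobile": 0.2, "sessile": 0.5}
    harder = sd.SimConfig(**QUIET, era_effort=low_effort)
    r_hi, _ = sd.generate_community(base, seed=11)
    r_lo, _ = sd.generate_community(harder, seed=11)

    def totals(rec):
        return rec.groupby(["era", "taxon"])["count"].sum()

    hi, lo = totals(r_hi), totals(r_lo)
    joined = pd.concat([hi, lo], axis=1, keys=["hi", "lo"]).fillna(0)
    assert (joined["lo"] <= joined["hi"]).all()
    era = joined.xs("1999-2015", level="era")
    assert era["lo"].sum() < era["hi"].sum()


def test_filter_report_matches_injected_quirks():
    cfg = sd.SimConfig()
    rec, truth = sd.generate_community(cfg, seed=3)
    rec2, _ = sv.harmonize_taxonomy(rec, truth.crosswalk)
    _, report = sv.apply_quantitative_filters(rec2, truth.crosswalk)
    observed = {s["step"]: s for s in report.steps}
    for step, injected in truth.quirk_counts.items():
        assert observed[step]["n_records_removed"] == injected["records"], step
        if "individuals" in injected and injected["individuals"]:
            assert observed[step]["n_individuals_removed"] == injected["individuals"], step


def test_clean_database_passes_filters_untouched():
    cfg = sd.SimConfig(**QUIET)
    rec, truth = sd.generate_community(cfg, seed=2)
    out, report = sv.apply_quantitative_filters(rec, truth.crosswalk)
    assert report.total_records_removed == 0
    assert len(out) == len(rec)


def test_range_class_trends_separate_lrr():
    from rockyshore import population_change as pc

    diffs = []
    for seed in range(5):
        cfg = sd.SimConfig(**QUIET)
        rec, truth = sd.generate_community(cfg, seed=seed)
        mat = sv.pool_site_year_matrix(rec)
        lrr = pc.compute_lrr(mat).set_index("taxon")
        classes = truth.taxa.set_index("taxon")["range_class"]
        lrr["range_class"] = classes.reindex(lrr.index)
        means = lrr.groupby("range_class")["mean_lrr"].mean()
        diffs.append(means["southern"] - means["coastwide"])
    assert np.mean(diffs) > 1.0  # southern taxa rise, coastwide fall


def test_infeasible_proportions_raise():
    with pytest.raises(ValueError, match="exceeds 1"):
        sd.generate_community(sd.SimConfig(prop_southern=0.6, prop_coastwide=0.6), seed=0)


def test_traits_consistent_with_true_range_classes():
    from rockyshore.population_change import assign_range_category

    cfg = sd.SimConfig(**QUIET)
    _, truth = sd.generate_community(cfg, seed=6)
    merged = truth.traits.merge(truth.taxa[["taxon", "range_class"]], on="taxon")
    for _, row in merged.iterrows():
        got = assign_range_category(row["northern_limit_lat"], row["southern_limit_lat"])
        assert got == row["range_class"]
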