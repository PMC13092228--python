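import numpy as np
import pandas as pd
import pytest

from rockyshore import survey_data as sv


def test_load_and_validate_well_formed(tmp_path, toy_records):
    path = tmp_path / "rec.csv"
    toy_records.to_csv(path, index=False)
    rec = sv.load_raw_records(path)
    assert len(rec) == 5
    assert rec["count"].notna().sum() == 4


def test_load_rejects_negative_count(tmp_path, toy_records):
    bad = toy_records.copy()
    bad.loc[0, "count"] = -1
    path = tmp_path / "rec.csv"
    bad.to_csv(path, index=False)
    with pytest.raises(sv.SurveyValidationError, match="negative or non-integer"):
        sv.load_raw_records(path)


def test_load_rejects_count_and_code_together(toy_records):
    bad = toy_records.copy()
    bad.loc[0, "qualitative_code"] = "rare"
    with pytest.raises(sv.SurveyValidationError, match="both count and qualitative_code"):
        sv.validate_records(bad)


def test_qualitative_only_record_has_absent_count(toy_records):
    rec = sv.validate_records(toy_records)
    qual = rec[rec["qualitative_code"].notna()]
    assert len(qual) == 1 and pd.isna(qual["count"]).all()


def test_load_drops_unanalyzed_era(tmp_path, toy_records):
    extra = pd.concat(
        [toy_records, pd.DataFrame([{"era": "1949", "year": 1949, "quadrat_id": "q12",
                                     "taxon": "Tegula funebralis", "count": 1,
                                     "qualitative_code": None, "date": None}])],
        ignore_index=True,
    )
    path = tmp_path / "rec.csv"
    extra.to_csv(path, index=False)
    with pytest.warns(UserWarning, match="unanalyzed eras"):
        rec = sv.load_raw_records(path)
    assert len(rec) == 5


def test_harmonize_renames_historical_synonym(toy_records, toy_crosswalk):
    rec, report = sv.harmonize_taxonomy(toy_records, toy_crosswalk)
    assert "Acanthina punctulata" not in set(rec["taxon"])
    assert "Acanthinucella punctulata" in set(rec["taxon"])
    # current names pass through unchanged and are not reported
    assert set(report["taxon_recorded"]) == {"Acanthina punctulata"}


def test_harmonize_strict_raises_on_unknown(toy_records, toy_crosswalk):
    with pytest.raises(sv.SurveyValidationError, match="Alia carinata"):
        sv.harmonize_taxonomy(toy_records, toy_crosswalk.iloc[1:], strict=True)
    rec, report = sv.harmonize_taxonomy(toy_records, toy_crosswalk.iloc[1:], strict=False)
    assert "unknown" in report.columns


def test_harmonize_never_increases_taxa(toy_records, toy_crosswalk):
    before = toy_records["taxon"].nunique()
    rec, _ = sv.harmonize_taxonomy(toy_records, toy_crosswalk)
    assert rec["taxon"].nunique() <= before


@pytest.fixture
def filter_fixture():
    """The four-rule hand trace: one keeper, three removals by distinct rules."""
    rows = [
        ("1993-1996", 1993, "q27", "Aaa speciesA", 5, None),
        ("1993-1996", 1993, "q27", "Bbb spp.", 2, None),        # genus, 2 congeners
        ("1993-1996", 1993, "q28", "Bbb speciesB1", 1, None),
        ("1993-1996", 1996, "q28", "Bbb speciesB2", 1, None),
        ("1993-1996", 1993, "q27", "CladeC", 9, None),           # above genus
        ("1993-1996", 1993, "q28", "Ddd speciesD", None, "rare"),  # never counted
    ]
    rec = pd.DataFrame(rows, columns=["era", "year", "quadrat_id", "taxon", "count", "qualitative_code"])
    rec["date"] = None
    cw = pd.DataFrame(
        [
            ("Aaa speciesA", "species", "mobile", False, True),
            ("Bbb spp.", "genus", "mobile", False, True),
            ("Bbb speciesB1", "species", "mobile", False, True),
            ("Bbb speciesB2", "species", "mobile", False, True),
            ("CladeC", "above_genus", "sessile", False, False),
            ("Ddd speciesD", "species", "mobile", False, True),
        ],
        columns=["analysis_taxon", "rank", "mobility", "epibiont", "on_baseline_list"],
    ).assign(taxon_recorded=lambda d: d["analysis_taxon"])
    return rec, cw


def test_filters_hand_trace(filter_fixture):
    rec, cw = filter_fixture
    out, report = sv.apply_quantitative_filters(rec, cw)
    kept = set(out["taxon"])
    assert kept == {"Aaa speciesA", "Bbb speciesB1", "Bbb speciesB2"}
    removed = {s["step"]: s["n_records_removed"] for s in report.steps}
    assert removed["qualitative_only_taxa"] == 1
    assert removed["above_genus_records"] == 1
    assert removed["genus_with_multiple_congeners"] == 1


def test_genus_with_single_congener_retained(filter_fixture):
    rec, cw = filter_fixture
    rec = rec[rec["taxon"] != "Bbb speciesB2"]
    out, _ = sv.apply_quantitative_filters(rec, cw)
    assert "Bbb spp." in set(out["taxon"])


def test_filters_idempotent(filter_fixture):
    rec, cw = filter_fixture
    once, rep1 = sv.apply_quantitative_filters(rec, cw)
    twice, rep2 = sv.apply_quantitative_filters(once, cw)
    pd.testing.assert_frame_equal(once, twice)
    assert rep2.total_records_removed == 0


def test_clean_input_identity(toy_crosswalk):
    rec = pd.DataFrame(
        [("1993-1996", 1993, "q27", "Tegula funebralis", 4, None, None)],
        columns=["era", "year", "quadrat_id", "taxon", "count", "qualitative_code", "date"],
    )
    out, report = sv.apply_quantitative_filters(rec, toy_crosswalk)
    assert len(out) == 1 and report.total_records_removed == 0


def test_pool_additivity_and_zeros():
    rec = pd.DataFrame(
        [
            ("1993-1996", 1993, "q27", "A a", 3, None, None),
            ("1993-1996", 1993, "q28", "A a", 4, None, None),
            ("1993-1996", 1996, "q27", "B b", 2, None, None),
        ],
        columns=["era", "year", "quadrat_id", "taxon", "count", "qualitative_code", "date"],
    )
    m = sv.pool_site_year_matrix(rec)
    assert m.counts.loc["1993", "A a"] == 7
    assert m.counts.loc["1996", "A a"] == 0
    assert m.total() == 9


def test_pool_conservation_brute_force(rng):
    taxa = ["T1", "T2"]
    rows = []
    for year in (1993, 1996):
        for q in sv.CORE_QUADRATS:
            for t in taxa:
                rows.append(("1993-1996", year, q, t, int(rng.integers(0, 9)), None, None))
    rec = pd.DataFrame(rows, columns=["era", "year", "quadrat_id", "taxon", "count", "qualitative_code", "date"])
    m = sv.pool_site_year_matrix(rec)
    assert m.counts.shape == (2, 2)
    assert m.total() == rec["count"].sum()
    for year in ("1993", "1996"):
        expected = rec[rec["year"].astype(str) == year]["count"].sum()
        assert m.counts.loc[year].sum() == expected


def test_pool_duplicate_rows_raise():
    rec = pd.DataFrame(
        [
            ("1993-1996", 1993, "q27", "A a", 3, None, None),
            ("1993-1996", 1993, "q27", "A a", 4, None, None),
        ],
        columns=["era", "year", "quadrat_id", "taxon", "count", "qualitative_code", "date"],
    )
    with pytest.raises(sv.SurveyValidationError, match="duplicate"):
        sv.pool_site_year_matrix(rec)
    m = sv.pool_site_year_matrix(rec, sum_duplicates=True)
    assert m.counts.loc["1993", "A a"] == 7


def test_density_per_square_metre():
    counts = pd.DataFrame({"A a": [76]}, index=["1993"])
    m = sv.SiteYearMatrix(counts=counts)
    out = sv.summarize_density_by_era(m, era_map={"1993": "1993-1996"})
    assert out.loc["1993-1996", ("density", "A a")] == pytest.approx(76 / (19 * 0.8361), abs=1e-3)
    assert out.loc["1993-1996", ("density", "A a")] == pytest.approx(4.784, abs=1e-3)


def test_density_sd_rules():
    counts = pd.DataFrame({"A a": [10, 10, 5]}, index=["1931-1933", "1993", "1996"])
    m = sv.SiteYearMatrix(counts=counts)
    era_map = {"1931-1933": "1931-1933", "1993": "1993-1996", "1996": "1993-1996"}
    out = sv.summarize_density_by_era(m, era_map=era_map)
    assert np.isnan(out.loc["1931-1933", ("sd", "A a")])  # single pooled baseline
    assert out.loc["1993-1996", ("sd", "A a")] > 0
    counts2 = pd.DataFrame({"A a": [7, 7]}, index=["1993", "1996"])
    out2 = sv.summarize_density_by_era(
        sv.SiteYearMatrix(counts=counts2), era_map={"1993": "1993-1996", "1996": "1993-1996"}
    )
    assert out2.loc["1993-1996", ("sd", "A a")] == 0
    with pytest.raises(ValueError):
        sv.summarize_density_by_era(m, era_map=era_map, quadrat_area_m2=0)
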