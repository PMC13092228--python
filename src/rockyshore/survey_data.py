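"""Ingestion, taxonomic harmonization, and filtering of multi-era survey records.

The Hewatt–Sagarin transect (Hopkins Marine Station, Pacific Grove, CA) has been
censused by a succession of investigators since 1931.  Raw records arrive as one
row per (era, year, quadrat, taxon) with either an integer count or a qualitative
abundance code.  This module validates those records, maps recorded names onto a
harmonized analysis taxonomy, applies the standard filters that prepare the data
for count-based diversity analysis, and pools counts to a site-year x taxon
matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ERA_SPANS",
    "QUALITATIVE_CODES",
    "FilterReport",
    "SiteYearMatrix",
    "SurveyValidationError",
    "apply_quantitative_filters",
    "era_of_year",
    "harmonize_taxonomy",
    "load_raw_records",
    "plot_occupancy",
    "pool_site_year_matrix",
    "summarize_density_by_era",
    "validate_records",
]

#: The five analyzed investigator eras (label -> inclusive year span).  The 1949
#: resurvey covered only 3 of the 19 core quadrats and is rejected at load time.
ERA_SPANS: dict[str, tuple[int, int]] = {
    "1931-1933": (1931, 1933),
    "1993-1996": (1993, 1996),
    "1999-2015": (1999, 2015),
    "2016-2019": (2016, 2019),
    "2020-2023": (2020, 2023),
}

BASELINE_ERA = "1931-1933"

QUALITATIVE_CODES = ("abundant", "common", "occasional", "rare")

#: Core quadrats resurveyed in every analyzed year (square-yard plots 27-38, 62-68).
CORE_QUADRATS = tuple(f"q{i}" for i in list(range(27, 39)) + list(range(62, 69)))

#: One square yard in square metres; quadrats are historical square-yard plots
#: but densities are reported per m^2.
SQUARE_YARD_M2 = 0.8361

RECORD_COLUMNS = ["era", "year", "date", "quadrat_id", "taxon", "count", "qualitative_code"]

CROSSWALK_COLUMNS = [
    "taxon_recorded",
    "analysis_taxon",
    "rank",
    "mobility",
    "epibiont",
    "on_baseline_list",
]


class SurveyValidationError(ValueError):
    """Raised when survey records violate a structural invariant."""


def era_of_year(year: int) -> str | None:
    """Return the era label containing ``year``, or None if unanalyzed."""
    for label, (lo, hi) in ERA_SPANS.items():
        if lo <= year <= hi:
            return label
    return None


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Check record invariants, raising :class:`SurveyValidationError` with row ids.

    Exactly one of count / qualitative_code per row; counts non-negative
    integers; qualitative codes from the four-level scale; year within its era.
    """
    rec = records.copy()
    problems: list[str] = []

    has_count = rec["count"].notna()
    has_code = rec["qualitative_code"].notna()
    both = rec.index[has_count & has_code]
    if len(both):
        problems.append(f"rows with both count and qualitative_code: {list(both)}")
    neither = rec.index[~has_count & ~has_code]
    if len(neither):
        problems.append(f"rows with neither count nor qualitative_code: {list(neither)}")

    counts = rec.loc[has_count, "count"]
    bad_count = counts.index[(counts < 0) | (counts != np.floor(counts))]
    if len(bad_count):
        problems.append(f"rows with negative or non-integer count: {list(bad_count)}")

    codes = rec.loc[has_code, "qualitative_code"]
    bad_code = codes.index[~codes.isin(QUALITATIVE_CODES)]
    if len(bad_code):
        problems.append(f"rows with unknown qualitative code: {list(bad_code)}")

    for idx, row in rec.iterrows():
        era = row["era"]
        if era not in ERA_SPANS:
            problems.append(f"row {idx}: unknown era {era!r}")
        else:
            lo, hi = ERA_SPANS[era]
            if not lo <= int(row["year"]) <= hi:
                problems.append(f"row {idx}: year {row['year']} outside era {era}")

    if problems:
        raise SurveyValidationError("; ".join(problems))
    return rec


def load_raw_records(path, schema: dict[str, str] | None = None) -> pd.DataFrame:
    """Load raw survey records from CSV and validate them.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Optional mapping from canonical column names (``era``, ``year``,
        ``quadrat_id``, ``taxon``, ``count``, ``qualitative_code``, ``date``)
        to the column names used in the file.

    Rows from unanalyzed eras (e.g. the 1949 partial resurvey) are dropped with
    a warning rather than an error.
    """
    raw = pd.read_csv(path)
    schema = schema or {}
    rename = {v: k for k, v in schema.items()}
    raw = raw.rename(columns=rename)

    required = {"era", "year", "quadrat_id", "taxon"}
    missing = required - set(raw.columns)
    if missing:
        raise KeyError(f"missing required columns: {sorted(missing)}")
    for col in ("count", "qualitative_code", "date"):
        if col not in raw.columns:
            raw[col] = np.nan

    unanalyzed = ~raw["era"].isin(ERA_SPANS)
    if unanalyzed.any():
        warnings.warn(
            f"dropping {int(unanalyzed.sum())} records from unanalyzed eras: "
            f"{sorted(raw.loc[unanalyzed, 'era'].unique())}",
            stacklevel=2,
        )
        raw = raw[~unanalyzed].copy()

    raw["qualitative_code"] = raw["qualitative_code"].where(
        raw["qualitative_code"].notna(), np.nan
    )
    return validate_records(raw[RECORD_COLUMNS])


def harmonize_taxonomy(
    records: pd.DataFrame, crosswalk: pd.DataFrame, strict: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace recorded names with harmonized analysis names.

    The crosswalk maps every historically recorded name to the currently
    accepted name used for analysis (e.g. records of *Acanthina punctulata*
    become *Acanthinucella punctulata*).  Returns the renamed records and a
    change report (one row per name actually changed, with record counts).

    With ``strict=True`` (default) unknown recorded names raise; otherwise they
    pass through unchanged and are flagged in the report with
    ``analysis_taxon == taxon_recorded`` and ``unknown == True``.
    """
    mapping = crosswalk.set_index("taxon_recorded")["analysis_taxon"]
    if mapping.index.has_duplicates:
        dupes = mapping.index[mapping.index.duplicated()].unique().tolist()
        raise SurveyValidationError(f"crosswalk maps names more than once: {dupes}")

    rec = records.copy()
    known = rec["taxon"].isin(mapping.index)
    if strict and not known.all():
        unknown = sorted(rec.loc[~known, "taxon"].unique())
        raise SurveyValidationError(f"recorded names missing from crosswalk: {unknown}")

    new_names = rec["taxon"].map(mapping).where(known, rec["taxon"])
    changed = new_names != rec["taxon"]
    report = (
        pd.DataFrame(
            {
                "taxon_recorded": rec.loc[changed, "taxon"],
                "analysis_taxon": new_names[changed],
            }
        )
        .value_counts()
        .rename("n_records")
        .reset_index()
    )
    unknown_names = sorted(rec.loc[~known, "taxon"].unique())
    if unknown_names:
        report = pd.concat(
            [
                report,
                pd.DataFrame(
                    {
                        "taxon_recorded": unknown_names,
                        "analysis_taxon": unknown_names,
                        "n_records": [int((rec["taxon"] == t).sum()) for t in unknown_names],
                    }
                ).assign(unknown=True),
            ],
            ignore_index=True,
        )
    rec["taxon"] = new_names
    return rec, report


@dataclass
class FilterReport:
    """Step-wise accounting of the quantitative-analysis filters, in order."""

    steps: list[dict] = field(default_factory=list)
    #: taxa on the baseline investigator's full species list that were never
    #: quantified there: retained as presence-only, excluded from count metrics
    presence_only_baseline: list[str] = field(default_factory=list)
    #: taxa first quantified after the baseline and absent from the baseline
    #: full list: treated as true zeros in the baseline
    explicit_zero_baseline: list[str] = field(default_factory=list)

    def add(self, step: str, removed: pd.DataFrame) -> None:
        self.steps.append(
            {
                "step": step,
                "n_records_removed": int(len(removed)),
                "n_individuals_removed": int(removed["count"].fillna(0).sum()),
                "taxa": sorted(removed["taxon"].unique()),
            }
        )

    @property
    def total_records_removed(self) -> int:
        return sum(s["n_records_removed"] for s in self.steps)

    def to_dict(self) -> dict:
        return {
            "steps": self.steps,
            "presence_only_baseline": self.presence_only_baseline,
            "explicit_zero_baseline": self.explicit_zero_baseline,
        }


def _genus_of(name: str) -> str:
    return str(name).split()[0]


def apply_quantitative_filters(
    records: pd.DataFrame,
    crosswalk: pd.DataFrame,
    genus_collapse_scope: str = "dataset",
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the four ordered filters preparing records for count-based analysis.

    In order: (a) drop taxa never counted anywhere (qualitative-only scores);
    (b) drop epibiont-flagged taxa (limpets living on trochid shells, not
    assessed in the baseline survey); (c) drop records identified above genus;
    (d) drop genus-level records when two or more species of that genus were
    also recorded (to avoid inflating richness).  Remaining qualitative records
    of otherwise-counted taxa are also dropped (counts only), and the baseline
    bookkeeping classifies never-quantified-at-baseline taxa as explicit zeros
    or presence-only depending on the baseline full species list.

    ``genus_collapse_scope`` is ``"dataset"`` (congeners counted anywhere
    trigger removal) or ``"era"`` (evaluated within each era separately).
    Filtering is idempotent: running it twice changes nothing.
    """
    meta = crosswalk.drop_duplicates("analysis_taxon").set_index("analysis_taxon")
    rec = records.copy()
    report = FilterReport()

    counted_ever = set(rec.loc[rec["count"].notna(), "taxon"])
    step_a = rec[~rec["taxon"].isin(counted_ever)]
    report.add("qualitative_only_taxa", step_a)
    rec = rec[rec["taxon"].isin(counted_ever)]

    epibionts = set(meta.index[meta["epibiont"].astype(bool)]) if len(meta) else set()
    step_b = rec[rec["taxon"].isin(epibionts)]
    report.add("epibiont_taxa", step_b)
    rec = rec[~rec["taxon"].isin(epibionts)]

    ranks = meta["rank"] if "rank" in meta else pd.Series(dtype=object)
    above = set(ranks.index[ranks == "above_genus"])
    step_c = rec[rec["taxon"].isin(above)]
    report.add("above_genus_records", step_c)
    rec = rec[~rec["taxon"].isin(above)]

    genus_taxa = set(ranks.index[ranks == "genus"])

    def _ambiguous_genera(frame: pd.DataFrame) -> set[str]:
        species = frame.loc[frame["taxon"].map(lambda t: t not in genus_taxa), "taxon"]
        n_species = species.groupby(species.map(_genus_of)).nunique()
        return set(n_species.index[n_species >= 2])

    if genus_collapse_scope == "dataset":
        ambiguous = _ambiguous_genera(rec)
        drop_mask = rec["taxon"].isin(genus_taxa) & rec["taxon"].map(
            lambda t: _genus_of(t) in ambiguous
        )
    elif genus_collapse_scope == "era":
        drop_mask = pd.Series(False, index=rec.index)
        for _, sub in rec.groupby("era"):
            amb = _ambiguous_genera(sub)
            drop_mask.loc[sub.index] = sub["taxon"].isin(genus_taxa) & sub["taxon"].map(
                lambda t: _genus_of(t) in amb
            )
    else:
        raise ValueError(f"unknown genus_collapse_scope: {genus_collapse_scope!r}")
    report.add("genus_with_multiple_congeners", rec[drop_mask])
    rec = rec[~drop_mask]

    # counts only from here on; drop stray qualitative scores of counted taxa
    qual_rows = rec[rec["count"].isna()]
    report.add("residual_qualitative_records", qual_rows)
    rec = rec[rec["count"].notna()].copy()

    # baseline bookkeeping for taxa never quantified in the baseline era
    baseline_taxa = set(rec.loc[rec["era"] == BASELINE_ERA, "taxon"])
    on_list = (
        meta["on_baseline_list"].astype(bool)
        if "on_baseline_list" in meta
        else pd.Series(dtype=bool)
    )
    for taxon in sorted(set(rec["taxon"]) - baseline_taxa):
        if taxon in on_list.index and bool(on_list.get(taxon, False)):
            report.presence_only_baseline.append(taxon)
        else:
            report.explicit_zero_baseline.append(taxon)

    if rec.empty:
        warnings.warn("no records remain after quantitative filtering", stacklevel=2)
    return rec, report


@dataclass
class SiteYearMatrix:
    """Site-year x taxon count matrix pooled over quadrats.

    ``counts`` is indexed by site-year label (the pooled baseline keeps its
    era label, recent years are calendar years as strings) with one column per
    harmonized taxon.  ``group_mask`` optionally classifies each taxon as
    mobile or sessile.
    """

    counts: pd.DataFrame
    group_mask: pd.Series | None = None

    @property
    def years(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    def abundances(self, year: str, group: str = "all") -> np.ndarray:
        """Per-taxon counts for one site-year, optionally restricted by mobility."""
        row = self.counts.loc[year]
        if group != "all":
            if self.group_mask is None:
                raise ValueError("group_mask required for mobility grouping")
            row = row[self.group_mask.reindex(row.index) == group]
        return row.to_numpy(dtype=np.int64)

    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def pool_site_year_matrix(
    records: pd.DataFrame,
    quadrat_set: tuple[str, ...] | list[str] = CORE_QUADRATS,
    sum_duplicates: bool = False,
    pool_baseline: bool = True,
    group_mask: pd.Series | None = None,
) -> SiteYearMatrix:
    """Pool counted records over quadrats into a site-year x taxon matrix.

    Only records from ``quadrat_set`` enter the pooling; site-years with no
    record from any quadrat of the set are dropped with a warning.  Duplicate
    (site-year, quadrat, taxon) rows raise unless ``sum_duplicates`` — silent
    summation would hide double data entry.  With ``pool_baseline`` the
    baseline-era years are pooled under the single label ``"1931-1933"``,
    matching the single unreplicated historical census.
    """
    rec = records[records["count"].notna()].copy()
    in_set = rec["quadrat_id"].isin(set(quadrat_set))
    lost_years = sorted(set(rec["year"]) - set(rec.loc[in_set, "year"]))
    if lost_years:
        warnings.warn(
            f"dropping site-years with no quadrat from the configured set: {lost_years}",
            stacklevel=2,
        )
    rec = rec[in_set]
    if rec.empty:
        raise SurveyValidationError("no counted records in the requested quadrat set")

    if pool_baseline:
        rec["site_year"] = np.where(
            rec["era"] == BASELINE_ERA, BASELINE_ERA, rec["year"].astype(str)
        )
    else:
        rec["site_year"] = rec["year"].astype(str)

    dup = rec.duplicated(["site_year", "quadrat_id", "taxon"], keep=False)
    if dup.any() and not sum_duplicates:
        offending = rec.loc[dup, ["site_year", "quadrat_id", "taxon"]].drop_duplicates()
        raise SurveyValidationError(
            "duplicate (site-year, quadrat, taxon) rows; pass sum_duplicates=True "
            f"to pool them:\n{offending.to_string(index=False)}"
        )

    counts = (
        rec.groupby(["site_year", "taxon"])["count"].sum().unstack(fill_value=0).astype(np.int64)
    )

    def _sort_key(label: str):
        return (0, 0) if label == BASELINE_ERA else (1, int(label))

    counts = counts.loc[sorted(counts.index, key=_sort_key)]
    if group_mask is not None:
        group_mask = group_mask.reindex(counts.columns)
    return SiteYearMatrix(counts=counts, group_mask=group_mask)


def plot_occupancy(records: pd.DataFrame) -> pd.Series:
    """Number of distinct quadrats in which each taxon was counted (>0), dataset-wide."""
    rec = records[(records["count"].notna()) & (records["count"] > 0)]
    return rec.groupby("taxon")["quadrat_id"].nunique()


def summarize_density_by_era(
    matrix: SiteYearMatrix,
    era_map: dict[str, str] | None = None,
    quadrat_area_m2: float = SQUARE_YARD_M2,
    n_quadrats: int = len(CORE_QUADRATS),
) -> pd.DataFrame:
    """Era x taxon mean density (individuals m^-2) with SD across years.

    Density per site-year = pooled count / (n_quadrats * quadrat_area_m2);
    within-era mean and SD follow.  Single-year eras (the pooled baseline)
    report SD as missing rather than zero.
    """
    if quadrat_area_m2 <= 0:
        raise ValueError("quadrat_area_m2 must be positive")
    if era_map is None:
        era_map = {
            y: (BASELINE_ERA if y == BASELINE_ERA else era_of_year(int(y)))
            for y in matrix.years
        }
    area = n_quadrats * quadrat_area_m2
    dens = matrix.counts / area
    dens["_era"] = [era_map[y] for y in dens.index]
    grouped = dens.groupby("_era")
    mean = grouped.mean()
    sd = grouped.std(ddof=1)  # NaN for single-year eras by construction
    out = pd.concat({"density": mean, "sd": sd}, axis=1)
    out.index.name = "era"
    return out
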