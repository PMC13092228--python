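"""Per-taxon log response ratios against the historical baseline.

Change in abundance for each taxon is summarized as the log response ratio
LRR = ln[(n_year + 1)/(n_baseline + 1)], computed per recent site-year against
the pooled 1931-1933 baseline census and averaged across years.  Taxa are
screened by an inclusion filter (total individuals and plot occupancy across
the whole dataset) and classified by geographic range against the two
biogeographic breakpoints of the northeast Pacific coast: Cape Mendocino and
Point Conception.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survey_data import BASELINE_ERA, SiteYearMatrix

__all__ = [
    "CAPE_MENDOCINO_LAT",
    "POINT_CONCEPTION_LAT",
    "apply_inclusion_filter",
    "assign_range_category",
    "compute_lrr",
    "range_contrast_inputs",
]

#: Biogeographic breakpoints (degrees N); the boundary capes of the analysis.
CAPE_MENDOCINO_LAT = 40.44
POINT_CONCEPTION_LAT = 34.45


@dataclass
class InclusionReport:
    retained: list[str]
    removed: pd.DataFrame  # taxon, total, n_plots, reason
    fraction_individuals_retained: float


def apply_inclusion_filter(
    matrix: SiteYearMatrix,
    plot_occupancy: pd.Series,
    min_individuals: int = 20,
    min_plots: int = 5,
) -> InclusionReport:
    """Retain taxa with >= min_individuals total and >= min_plots occupied plots.

    Both thresholds are inclusive (a taxon with exactly 20 individuals in
    exactly 5 plots stays).  Occupancy is evaluated dataset-wide.
    """
    totals = matrix.counts.sum(axis=0)
    occ = plot_occupancy.reindex(matrix.taxa).fillna(0).astype(int)
    keep = (totals >= min_individuals) & (occ >= min_plots)
    removed_rows = []
    for taxon in totals.index[~keep]:
        reasons = []
        if totals[taxon] < min_individuals:
            reasons.append(f"total {int(totals[taxon])} < {min_individuals}")
        if occ[taxon] < min_plots:
            reasons.append(f"plots {int(occ[taxon])} < {min_plots}")
        removed_rows.append(
            dict(taxon=taxon, total=int(totals[taxon]), n_plots=int(occ[taxon]),
                 reason="; ".join(reasons))
        )
    frac = float(totals[keep].sum() / totals.sum()) if totals.sum() else 0.0
    return InclusionReport(
        retained=list(totals.index[keep]),
        removed=pd.DataFrame(removed_rows, columns=["taxon", "total", "n_plots", "reason"]),
        fraction_individuals_retained=frac,
    )


def lrr(n_year: float, n_baseline: float) -> float:
    """ln[(n_year + 1)/(n_baseline + 1)]; defined for all non-negative counts."""
    return float(np.log((n_year + 1.0) / (n_baseline + 1.0)))


def compute_lrr(
    matrix: SiteYearMatrix,
    baseline_label: str = BASELINE_ERA,
    recent_labels: list[str] | None = None,
    taxa: list[str] | None = None,
    ci_method: str = "normal",
    n_boot: int = 2000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean LRR per taxon across recent site-years, with SE and 95% CI.

    SE is the standard error of the yearly LRR values (sd / sqrt(n_years)).
    ``ci_method`` 'normal' gives mean +/- 1.96 SE; 'bootstrap' resamples years
    with replacement (percentile interval) since the normal form is only an
    approximation for short series.
    """
    if baseline_label not in matrix.counts.index:
        raise KeyError(f"baseline {baseline_label!r} not in matrix")
    recent = recent_labels or [y for y in matrix.years if y != baseline_label]
    if not recent:
        raise ValueError("no recent site-years to compare against the baseline")
    cols = taxa or matrix.taxa
    base = matrix.counts.loc[baseline_label, cols].to_numpy(dtype=float)
    recent_counts = matrix.counts.loc[recent, cols].to_numpy(dtype=float)
    per_year = np.log((recent_counts + 1.0) / (base[None, :] + 1.0))
    mean = per_year.mean(axis=0)
    n_years = per_year.shape[0]
    sd = per_year.std(axis=0, ddof=1) if n_years > 1 else np.zeros_like(mean)
    se = sd / np.sqrt(n_years)
    if ci_method == "normal":
        lo, hi = mean - 1.96 * se, mean + 1.96 * se
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = np.empty((n_boot, len(cols)))
        for b in range(n_boot):
            idx = rng.integers(0, n_years, n_years)
            boots[b] = per_year[idx].mean(axis=0)
        lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    else:
        raise ValueError(f"unknown ci_method: {ci_method!r}")
    return pd.DataFrame(
        {
            "taxon": cols,
            "n_baseline": base.astype(int),
            "n_years": n_years,
            "mean_lrr": mean,
            "se": se,
            "lrr_lo": lo,
            "lrr_hi": hi,
        }
    )


def assign_range_category(
    northern_limit_lat: float | None,
    southern_limit_lat: float | None,
    cape_mendocino_lat: float = CAPE_MENDOCINO_LAT,
    point_conception_lat: float = POINT_CONCEPTION_LAT,
) -> str:
    """Classify a taxon's geographic range: southern / northern / coastwide / uncertain.

    Northern range limit south of Cape Mendocino -> southern; southern limit
    north of Point Conception -> northern; limits extending beyond both
    breakpoints -> coastwide; insufficient information -> uncertain.  A range
    nested entirely between the two capes fires both rules and raises.
    """

    def known(v):
        return v is not None and np.isfinite(v)

    if known(northern_limit_lat) and known(southern_limit_lat):
        if northern_limit_lat < southern_limit_lat:
            raise ValueError("northern limit south of southern limit")
    south_fires = known(northern_limit_lat) and northern_limit_lat < cape_mendocino_lat
    north_fires = known(southern_limit_lat) and southern_limit_lat > point_conception_lat
    if south_fires and north_fires:
        raise ValueError(
            "range lies entirely between Point Conception and Cape Mendocino; "
            "southern and northern rules both fire"
        )
    if south_fires:
        return "southern"
    if north_fires:
        return "northern"
    if (
        known(northern_limit_lat)
        and known(southern_limit_lat)
        and northern_limit_lat >= cape_mendocino_lat
        and southern_limit_lat <= point_conception_lat
    ):
        return "coastwide"
    return "uncertain"


def range_contrast_inputs(
    records: pd.DataFrame, se_floor: float = 1e-3
) -> pd.DataFrame:
    """Prepare LRR records for the range-class measurement-error model.

    ``records`` needs columns taxon, mean_lrr, se, range_class.  Uncertain-
    class taxa are excluded from the contrast but kept in the output, flagged;
    zero SEs are floored (and flagged) to avoid a degenerate likelihood.
    """
    if records.empty:
        raise ValueError("no LRR records supplied")
    out = records.copy()
    out["in_contrast"] = out["range_class"].isin(["coastwide", "southern"])
    out["se_floored"] = out["se"] < se_floor
    out["obs_mean"] = out["mean_lrr"]
    out["se"] = out["se"].clip(lower=se_floor)
    for label in ("coastwide", "southern"):
        if not ((out["range_class"] == label) & out["in_contrast"]).any():
            raise ValueError(f"range class {label!r} empty after exclusions")
    return out
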