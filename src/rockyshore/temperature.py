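"""Sea-surface-temperature covariates for survey years.

The attribution models use an extreme-temperature covariate: the empirical
90th percentile of daily SST over the 365-day window ending the day before
each survey, so that the hypothesized cause precedes the measured effect.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureCovariate",
    "covariates_for_surveys",
    "load_temperature_series",
    "max_sst_p90",
]

log = logging.getLogger(__name__)

#: Quantile convention used throughout, recorded in outputs for auditability.
QUANTILE_METHOD = "linear"


@dataclass
class TemperatureCovariate:
    year: int
    t_max_p90: float  # degC; NaN when the window is too sparse
    window_start: date
    window_end: date
    n_days_used: int
    quantile_method: str = QUANTILE_METHOD

    @property
    def missing(self) -> bool:
        return not np.isfinite(self.t_max_p90)


def load_temperature_series(path) -> pd.DataFrame:
    """Read a daily SST series (columns date, sst_c); sort and validate."""
    df = pd.read_csv(path, parse_dates=["date"])
    df["date"] = df["date"].dt.date
    return validate_series(df)


def validate_series(series: pd.DataFrame) -> pd.DataFrame:
    df = series.sort_values("date").reset_index(drop=True)
    if df["date"].duplicated().any():
        dupes = df.loc[df["date"].duplicated(), "date"].unique()[:5]
        raise ValueError(f"duplicate dates in temperature series, e.g. {list(dupes)}")
    if not np.isfinite(df["sst_c"].dropna()).all():
        raise ValueError("non-finite temperatures present")
    return df


def max_sst_p90(
    series: pd.DataFrame, survey_ref_date: date, min_days: int = 200
) -> TemperatureCovariate:
    """90th percentile of daily SST in the 365 days before ``survey_ref_date``.

    The window is [ref - 365 d, ref - 1 d].  Fewer than ``min_days``
    observations yields a missing covariate with a warning (hand-collected
    series have gaps, and a percentile over sparse coverage misleads).
    """
    window_end = survey_ref_date - timedelta(days=1)
    window_start = survey_ref_date - timedelta(days=365)
    dates = series["date"]
    mask = (dates >= window_start) & (dates <= window_end)
    vals = series.loc[mask, "sst_c"].dropna().to_numpy()
    year = survey_ref_date.year
    if vals.size < min_days:
        warnings.warn(
            f"survey year {year}: only {vals.size} SST days in "
            f"[{window_start}, {window_end}] (< {min_days}); covariate missing",
            stacklevel=2,
        )
        return TemperatureCovariate(year, float("nan"), window_start, window_end, int(vals.size))
    p90 = float(np.quantile(vals, 0.9, method=QUANTILE_METHOD))
    return TemperatureCovariate(year, p90, window_start, window_end, int(vals.size))


def covariates_for_surveys(
    series: pd.DataFrame, survey_dates: dict[int, date], min_days: int = 200
) -> pd.DataFrame:
    """One prior-year p90 covariate per survey year.

    ``survey_dates`` maps survey year -> first survey date that year; when the
    survey day is unknown, pass January 1 of the survey year so the window
    falls back to the prior calendar year.  Years whose window is too sparse
    appear with a missing value and are logged for downstream exclusion.
    """
    if not survey_dates:
        raise ValueError("no survey dates supplied")
    rows = []
    for year in sorted(survey_dates):
        cov = max_sst_p90(series, survey_dates[year], min_days=min_days)
        cov.year = year
        if cov.missing:
            log.info("year %d excluded from attribution: SST window too sparse", year)
        rows.append(
            dict(
                year=year,
                t_max_p90=cov.t_max_p90,
                window_start=cov.window_start,
                window_end=cov.window_end,
                n_days_used=cov.n_days_used,
                quantile_method=cov.quantile_method,
            )
        )
    return pd.DataFrame(rows)
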