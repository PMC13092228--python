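"""The 'language of evidence': graded statements instead of binary significance.

Effects are communicated as strong / moderate / weak / none based on (i) the
posterior probability that a slope has a given sign (thresholds 95%, 90%,
80%), (ii) overlap of 95% and 80% credible intervals (non-overlap at 95% is
strong, at 80% weak), and (iii) a baseline-envelope test: strong evidence of
change when no recent-year 95% predictive interval contains the historical
baseline value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EvidenceStatement",
    "baseline_envelope_test",
    "classify_interval_evidence",
    "classify_slope_evidence",
    "count_strong_changes",
    "prob_of_sign",
]

SIGN_THRESHOLDS = {"strong": 0.95, "moderate": 0.90, "weak": 0.80}


@dataclass
class EvidenceStatement:
    subject: str
    grade: str  # strong | moderate | weak | none
    basis: str  # sign_probability | interval_overlap | baseline_envelope
    support: dict


def prob_of_sign(draws, direction: str = "negative") -> float:
    """Fraction of posterior draws with the stated sign (zeros count to neither)."""
    arr = np.asarray(draws, dtype=float)
    if arr.size == 0:
        raise ValueError("empty posterior sample")
    if arr.size < 1000:
        import warnings

        warnings.warn(f"only {arr.size} draws; sign probability is noisy", stacklevel=2)
    if direction == "negative":
        return float(np.mean(arr < 0))
    if direction == "positive":
        return float(np.mean(arr > 0))
    raise ValueError("direction must be 'negative' or 'positive'")


def classify_slope_evidence(p_sign: float) -> str:
    """Grade a sign probability: >=0.95 strong, >=0.90 moderate, >=0.80 weak."""
    if not 0.0 <= p_sign <= 1.0:
        raise ValueError("p_sign must be a probability")
    for grade, thr in SIGN_THRESHOLDS.items():
        if p_sign >= thr:
            return grade
    return "none"


def _check_nested(ci95, ci80):
    if not (ci95[0] <= ci80[0] <= ci80[1] <= ci95[1]):
        raise ValueError(f"80% interval {ci80} not nested inside 95% interval {ci95}")


def _disjoint(a, b) -> bool:
    return a[1] < b[0] or b[1] < a[0]


def classify_interval_evidence(a95, a80, b95, b80=None) -> str:
    """Grade two estimates by credible-interval overlap.

    ``b95``/``b80`` may be a point value (compare an interval against zero).
    Disjoint 95% intervals -> strong; else disjoint 80% -> weak; else none.
    """
    _check_nested(a95, a80)
    if np.isscalar(b95):
        b95 = (float(b95), float(b95))
        b80 = b95
    else:
        if b80 is None:
            raise ValueError("b80 required when b is an interval")
        _check_nested(b95, b80)
    if _disjoint(a95, b95):
        return "strong"
    if _disjoint(a80, b80):
        return "weak"
    return "none"


def baseline_envelope_test(intervals: pd.DataFrame, baseline: float) -> dict:
    """Does the recent record predict the historical baseline?

    ``intervals`` has columns year, pi_low, pi_high (95% posterior-predictive
    bounds).  Containment uses closed intervals — a baseline equal to a bound
    counts as contained, conservative toward 'no change'.  Overall grade is
    'strong' only when no year contains the baseline; otherwise the last
    containing year is reported so statements like "change after 1999" fall
    out directly.
    """
    if intervals.empty:
        raise ValueError("no predictive intervals supplied")
    df = intervals.sort_values("year").reset_index(drop=True)
    contains = (df["pi_low"] <= baseline) & (baseline <= df["pi_high"])
    last_containing = df.loc[contains, "year"].max() if contains.any() else None
    return {
        "per_year": pd.DataFrame({"year": df["year"], "contains_baseline": contains}),
        "grade": "strong" if not contains.any() else "none",
        "n_years": int(len(df)),
        "n_containing": int(contains.sum()),
        "change_after": last_containing,
    }


def count_strong_changes(table: pd.DataFrame) -> dict:
    """Count taxa whose 95% CI for the log response ratio excludes zero.

    ``table`` needs columns ``lrr_lo`` and ``lrr_hi``.  Two conventions are
    always reported: ``strict`` treats a printed bound equal to 0.0 as touching
    zero (not strong); ``rounded`` treats it as a rounded positive/negative
    value (strong), since tables printed to one decimal round small nonzero
    bounds to 0.0.  Each convention reports (n_strong, n_declines,
    n_increases).
    """
    lo = table["lrr_lo"].to_numpy(dtype=float)
    hi = table["lrr_hi"].to_numpy(dtype=float)
    if np.isnan(lo).any() or np.isnan(hi).any():
        raise ValueError("CI bounds missing for some taxa")

    def _counts(declines, increases):
        return {
            "n_strong": int(np.sum(declines | increases)),
            "n_declines": int(np.sum(declines)),
            "n_increases": int(np.sum(increases)),
        }

    strict = _counts(hi < 0, lo > 0)
    # rounded mode: a printed bound of exactly 0.0 is read as a rounded small
    # value of the sign of the interval; the degenerate (0, 0) interval is
    # exactly zero and counts as neither
    rounded = _counts((hi <= 0) & (lo < 0), (lo >= 0) & (hi > 0))
    return {"strict": strict, "rounded": rounded, "n_taxa": int(len(table))}
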