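import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rockyshore import diversity as dv
from rockyshore.survey_data import SiteYearMatrix

abundances = st.lists(st.integers(min_value=1, max_value=60), min_size=2, max_size=25)


def exhaustive_rarefaction(x, m):
    """Average richness over every distinct m-subset of labelled individuals."""
    individuals = [i for i, c in enumerate(x) for _ in range(c)]
    total, count = 0, 0
    for combo in itertools.combinations(individuals, m):
        total += len(set(combo))
        count += 1
    return total / count


@pytest.mark.parametrize(
    "x,q,expected",
    [
        ([10, 10, 10], 0, 3.0),
        ([10, 10, 10], 1, 3.0),
        ([10, 10, 10], 2, 3.0),
        ([8, 1, 1], 1, 1.8946),
        ([8, 1, 1], 2, 1.51515),
    ],
)
def test_hill_number_closed_forms(x, q, expected):
    assert dv.hill_number(x, q) == pytest.approx(expected, abs=2e-4)


def test_hill_number_empty_sample_undefined():
    with pytest.raises(dv.UndefinedMetric):
        dv.hill_number([0, 0], 1)


@given(abundances)
@settings(max_examples=60, deadline=None)
def test_hill_continuity_at_q1(x):
    d1 = dv.hill_number(x, 1)
    for q in (1 - 1e-7, 1 + 1e-7):
        assert dv.hill_number(x, q) == pytest.approx(d1, abs=1e-6)


@given(abundances)
@settings(max_examples=60, deadline=None)
def test_hill_ordering_in_q(x):
    d0, d1, d2 = (dv.hill_number(x, q) for q in (0, 1, 2))
    assert d0 + 1e-9 >= d1 >= d2 - 1e-9
    assert d2 >= 1.0


@pytest.mark.parametrize(
    "x,expected",
    [([2, 2], 1.0), ([4, 3, 2, 1], 0.91818), ([1], 0.0)],
)
def test_coverage_closed_forms(x, expected):
    assert dv.estimate_coverage(x) == pytest.approx(expected, abs=1e-5)


def test_rarefaction_exact_against_enumeration():
    """E[S_m] matches exhaustive subsample enumeration for n <= 12."""
    cases = [([4, 3, 2, 1], 5), ([4, 3, 2, 1], 9), ([5, 4, 3], 6), ([1, 1, 1, 1], 2), ([6, 3, 2, 1], 4)]
    for x, m in cases:
        assert dv.rarefy_richness(x, m) == pytest.approx(exhaustive_rarefaction(x, m), abs=1e-9)
    assert dv.rarefy_richness([4, 3, 2, 1], 5) == pytest.approx(3.17063, abs=1e-5)


def test_rarefaction_monte_carlo_for_larger_n(rng):
    x = rng.integers(1, 40, size=30)
    n = int(x.sum())
    m = n // 3
    labels = np.repeat(np.arange(x.size), x)
    draws = 50_000
    richness = np.empty(draws)
    for b in range(draws):
        richness[b] = np.unique(rng.choice(labels, size=m, replace=False)).size
    mc_mean, mc_se = richness.mean(), richness.std(ddof=1) / math.sqrt(draws)
    assert dv.rarefy_richness(x, m) == pytest.approx(mc_mean, abs=3 * mc_se)


def test_rarefaction_boundaries():
    x = [4, 3, 2, 1]
    assert dv.rarefy_richness(x, 10) == pytest.approx(4.0, abs=1e-9)
    assert dv.rarefy_richness(x, 1) == pytest.approx(1.0, abs=1e-9)
    with pytest.raises(ValueError):
        dv.rarefy_richness(x, 11)


@given(abundances)
@settings(max_examples=40, deadline=None)
def test_coverage_monotone_in_m(x):
    v = dv.AbundanceVector(x)
    cs = [dv.coverage_at_size(v, m) for m in range(1, v.n + 1)]
    assert all(b >= a - 1e-12 for a, b in zip(cs, cs[1:]))
    assert 0.0 <= cs[0] and cs[-1] <= 1.0


def test_estimate_at_reference_coverage_is_observed():
    x = [12, 8, 5, 3, 2, 2, 1]
    c_ref = dv.estimate_coverage(x)
    est = dv.estimate_at_coverage(x, c_ref, q=0, n_boot=0)
    assert est.basis == "observed"
    assert est.value == pytest.approx(dv.AbundanceVector(x).s_obs)


def test_estimate_at_coverage_consistent_with_rarefaction():
    x = [4, 3, 2, 1]
    target = dv.coverage_at_size(x, 5)
    est = dv.estimate_at_coverage(x, target, q=0, n_boot=0)
    assert est.m == 5 and est.value == pytest.approx(3.17063, abs=1e-5)


def test_bootstrap_reproducible_and_deterministic_point():
    x = [40, 30, 20, 10, 5, 2, 1, 1]
    a = dv.estimate_at_coverage(x, 0.97, q=1, n_boot=100, seed=7)
    b = dv.estimate_at_coverage(x, 0.97, q=1, n_boot=100, seed=7)
    assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
    c = dv.estimate_at_coverage(x, 0.97, q=1, n_boot=0)
    assert c.value == a.value


def test_extrapolation_cap_for_richness():
    x = [3, 1, 1, 1, 1, 1]  # coverage far from 1; high target needs huge m
    with pytest.raises(dv.UndefinedMetric, match="lower target"):
        dv.estimate_at_coverage(x, 0.999, q=0, n_boot=0)


@pytest.mark.parametrize(
    "x,expected",
    [([5, 5, 5], 1.0), ([8, 1, 1], 0.4473)],
)
def test_evenness_values(x, expected):
    assert dv.evenness(x) == pytest.approx(expected, abs=2e-4)


def test_evenness_dominance_monotone_and_domain():
    assert dv.evenness([98, 1, 1]) < dv.evenness([8, 1, 1])
    assert dv.evenness([98, 1, 1]) > 0
    with pytest.raises(dv.UndefinedMetric):
        dv.evenness([5])


def test_time_series_exchangeable_years_and_dominance_ordering():
    counts = pd.DataFrame(
        {
            "A": [25, 25, 60, 85],
            "B": [25, 25, 20, 5],
            "C": [25, 25, 10, 5],
            "D": [25, 25, 10, 5],
        },
        index=["1993", "1996", "1999", "2002"],
    )
    out = dv.diversity_time_series(SiteYearMatrix(counts=counts), n_boot=0)
    piv = out.pivot(index="year", columns="metric", values="estimate")
    # identical columns -> identical estimates
    assert piv.loc["1993"].equals(piv.loc["1996"])
    # increasing dominance at constant richness: q0 flat, q1/q2/evenness fall
    assert piv["q0"].nunique() == 1
    for metric in ("q1", "q2", "evenness"):
        vals = piv.loc[["1996", "1999", "2002"], metric].to_numpy()
        assert np.all(np.diff(vals) < 0)


def test_time_series_empty_group_year_is_missing():
    counts = pd.DataFrame({"A": [10, 0], "B": [5, 0]}, index=["1993", "1996"])
    mask = pd.Series({"A": "mobile", "B": "mobile"})
    out = dv.diversity_time_series(
        SiteYearMatrix(counts=counts, group_mask=mask), grouping="mobile", n_boot=0
    )
    empty = out[out["year"] == "1996"]
    assert empty["basis"].eq("missing").all()
    assert empty["estimate"].isna().all()
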