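"""Hill numbers, sample coverage, and coverage-standardized rarefaction/extrapolation.

Hill numbers express diversity of order q as an effective number of equally
abundant taxa: q=0 is richness, q=1 (Hill-Shannon) weights taxa by abundance,
q=2 (Hill-Simpson) emphasizes dominants.  Because the number of individuals
per site-year census varies strongly, raw Hill numbers confound community
change with sampling effort; estimates are therefore standardized to a common
sample *coverage* (the probability that the next individual sampled belongs to
an already-observed taxon) via rarefaction below the reference sample size and
the standard asymptotic extrapolations above it, with a percentile bootstrap
for uncertainty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .survey_data import SiteYearMatrix

__all__ = [
    "AbundanceVector",
    "DiversityEstimate",
    "UndefinedMetric",
    "coverage_at_size",
    "diversity_time_series",
    "estimate_at_coverage",
    "estimate_coverage",
    "evenness",
    "hill_number",
    "hill_at_size",
    "rarefy_richness",
    "size_for_coverage",
]


class UndefinedMetric(ValueError):
    """Signals a metric that is undefined for the input (e.g. empty sample)."""


@dataclass(frozen=True)
class AbundanceVector:
    """Per-taxon counts with the tallies coverage estimation needs."""

    x: np.ndarray

    def __init__(self, x) -> None:
        arr = np.asarray(x, dtype=np.int64)
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "x", arr[arr > 0])

    @property
    def n(self) -> int:
        return int(self.x.sum())

    @property
    def s_obs(self) -> int:
        return int(self.x.size)

    @property
    def f1(self) -> int:
        return int((self.x == 1).sum())

    @property
    def f2(self) -> int:
        return int((self.x == 2).sum())

    @property
    def p(self) -> np.ndarray:
        if self.n == 0:
            raise UndefinedMetric("relative abundances undefined for empty sample")
        return self.x / self.n


@dataclass
class DiversityEstimate:
    """A Hill number standardized to a target coverage, with bootstrap bounds."""

    q: float
    value: float
    coverage_target: float
    m: int
    basis: str  # observed | rarefied | extrapolated
    ci_low: float = np.nan
    ci_high: float = np.nan


def _as_vector(x) -> AbundanceVector:
    return x if isinstance(x, AbundanceVector) else AbundanceVector(x)


def hill_number(x, q: float) -> float:
    """Hill diversity of order q for observed relative abundances.

    q=0 returns observed richness; q=1 the exponential of Shannon entropy;
    otherwise (sum p_i^q)^(1/(1-q)).
    """
    v = _as_vector(x)
    if v.n == 0:
        raise UndefinedMetric("Hill number undefined for empty sample")
    if q == 0:
        return float(v.s_obs)
    p = v.p
    if q == 1:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def estimate_coverage(x) -> float:
    """Estimated sample coverage of the reference sample (Chao–Jost estimator).

    C-hat = 1 - (f1/n) * [(n-1) f1 / ((n-1) f1 + 2 f2)].
    """
    v = _as_vector(x)
    n, f1, f2 = v.n, v.f1, v.f2
    if n == 0:
        raise UndefinedMetric("coverage undefined for empty sample")
    if f1 == 0:
        return 1.0
    denom = (n - 1) * f1 + 2 * f2
    frac = 1.0 if denom == 0 else (n - 1) * f1 / denom
    return float(1.0 - (f1 / n) * frac)


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefy_richness(x, m: int) -> float:
    """Expected richness in a subsample of size m (exact hypergeometric form).

    E[S_m] = sum_i [1 - C(n - x_i, m) / C(n, m)], evaluated in log space.
    """
    v = _as_vector(x)
    n = v.n
    if not 1 <= m <= n:
        raise ValueError(f"m must be in [1, n={n}]; use extrapolation beyond n")
    xi = v.x
    keep = (n - xi) >= m
    ratio = np.zeros(v.s_obs)
    if keep.any():
        ratio[keep] = np.exp(_log_comb(n - xi[keep], m) - _log_comb(n, m))
    return float(np.sum(1.0 - ratio))


def _f0_hat(v: AbundanceVector) -> float:
    """Bias-corrected Chao1 estimate of the number of undetected taxa."""
    n, f1, f2 = v.n, v.f1, v.f2
    if n <= 1 or f1 == 0:
        return 0.0
    if f2 > 0:
        return (n - 1) / n * f1 * f1 / (2.0 * f2)
    return (n - 1) / n * f1 * (f1 - 1) / 2.0


def _chao_jost_A(v: AbundanceVector) -> float:
    n, f1, f2 = v.n, v.f1, v.f2
    if f2 > 0:
        return 2.0 * f2 / ((n - 1) * f1 + 2.0 * f2)
    if f1 > 1:
        return 2.0 / ((n - 1) * (f1 - 1) + 2.0)
    return 1.0


def _shannon_asymptotic(v: AbundanceVector) -> float:
    """Chao–Jost nearly unbiased estimator of asymptotic Shannon entropy."""
    n, xi, f1 = v.n, v.x, v.f1
    if n <= 1:
        return 0.0
    ks = np.arange(1, n)
    inv = 1.0 / ks
    cum = np.concatenate([[0.0], np.cumsum(inv)])  # cum[j] = sum_{k=1..j} 1/k
    part1 = 0.0
    sub = xi[xi <= n - 1]
    part1 = float(np.sum(sub / n * (cum[n - 1] - cum[sub - 1])))
    A = _chao_jost_A(v)
    part2 = 0.0
    if f1 > 0 and A < 1.0:
        r = np.arange(1, n)
        part2 = (
            f1
            / n
            * (1.0 - A) ** (1 - n)
            * (-math.log(A) - float(np.sum((1.0 - A) ** r / r)))
        )
    return part1 + part2


def coverage_at_size(x, m: int) -> float:
    """Expected coverage of a sample of size m (interpolated or extrapolated)."""
    v = _as_vector(x)
    n = v.n
    if n == 0:
        raise UndefinedMetric("coverage undefined for empty sample")
    if m < 1:
        raise ValueError("m must be >= 1")
    if m < n:
        xi = v.x
        keep = (n - xi) >= m
        term = np.zeros(v.s_obs)
        if keep.any():
            term[keep] = np.exp(
                np.log(xi[keep] / n) + _log_comb(n - xi[keep], m) - _log_comb(n - 1, m)
            )
        return float(1.0 - np.sum(term))
    if m == n:
        return estimate_coverage(v)
    # extrapolation: C(n + m*) = 1 - (f1/n) * Aprime^(m*+1)
    f1, f2 = v.f1, v.f2
    if f1 == 0:
        return 1.0
    denom = (n - 1) * f1 + 2 * f2
    aprime = 0.0 if denom == 0 else (n - 1) * f1 / denom
    return float(1.0 - (f1 / n) * aprime ** (m - n + 1))


def size_for_coverage(x, target_c: float, cap: int | None = None) -> tuple[int, str]:
    """Smallest sample size whose expected coverage reaches ``target_c``.

    Returns (m, basis) with basis 'rarefied'/'observed'/'extrapolated'.  A cap
    (e.g. twice the reference size for q=0) bounds extrapolation; an
    unreachable target raises with advice to lower it.
    """
    v = _as_vector(x)
    n = v.n
    if not 0 < target_c <= 1:
        raise ValueError("target coverage must be in (0, 1]")
    c_ref = estimate_coverage(v)
    if target_c <= c_ref:
        lo, hi = 1, n
        while lo < hi:  # coverage_at_size is non-decreasing in m
            mid = (lo + hi) // 2
            if coverage_at_size(v, mid) >= target_c:
                hi = mid
            else:
                lo = mid + 1
        return lo, ("observed" if lo == n else "rarefied")
    f1, f2 = v.f1, v.f2
    if f1 == 0:
        return n, "observed"
    if f2 > 0:
        aprime = (n - 1) * f1 / ((n - 1) * f1 + 2 * f2)
    elif f1 > 1:  # bias-corrected substitution f2 -> (f1 - 1)/2
        aprime = (n - 1) * (f1 - 1) / ((n - 1) * (f1 - 1) + 2)
    else:
        raise UndefinedMetric("coverage cannot be extrapolated (no doubleton signal)")
    if aprime <= 0 or aprime >= 1:
        raise UndefinedMetric("coverage cannot be extrapolated (degenerate tail)")
    mstar = math.log(n * (1.0 - target_c) / f1) / math.log(aprime) - 1.0
    m = n + max(1, math.ceil(mstar))
    if cap is not None and m > cap:
        raise UndefinedMetric(
            f"target coverage {target_c:.4f} needs m={m} beyond the extrapolation "
            f"cap {cap}; choose a lower target"
        )
    return m, "extrapolated"


def _hill_shannon_at_size(v: AbundanceVector, m: int) -> float:
    n, xi = v.n, v.x
    if m >= n:
        h_obs = math.log(hill_number(v, 1))
        if m == n:
            return math.exp(h_obs)
        h_inf = max(_shannon_asymptotic(v), h_obs)
        w = n / m
        return math.exp(w * h_obs + (1.0 - w) * h_inf)
    # interpolation: H(m) = sum_k -(k/m) log(k/m) * sum_i P[X_i = k | hypergeom]
    log_cnm = _log_comb(n, m)
    h = 0.0
    for x_i in xi:
        k_lo = max(1, m - (n - x_i))
        k_hi = min(x_i, m)
        if k_hi < k_lo:
            continue
        k = np.arange(k_lo, k_hi + 1)
        logp = _log_comb(x_i, k) + _log_comb(n - x_i, m - k) - log_cnm
        frac = k / m
        h += float(np.sum(np.exp(logp) * (-frac * np.log(frac))))
    return math.exp(h)


def _hill_simpson_at_size(v: AbundanceVector, m: int) -> float:
    n, xi = v.n, v.x
    if n < 2 or m < 1:
        raise UndefinedMetric("Hill-Simpson standardization needs n >= 2, m >= 1")
    s2 = float(np.sum(xi * (xi - 1.0)) / (n * (n - 1.0)))
    return 1.0 / (1.0 / m + (1.0 - 1.0 / m) * s2)


def hill_at_size(x, m: int, q: float) -> float:
    """Hill number of order q in {0, 1, 2} standardized to sample size m."""
    v = _as_vector(x)
    n = v.n
    if n == 0:
        raise UndefinedMetric("empty sample")
    if q == 0:
        if m <= n:
            return rarefy_richness(v, m)
        f0 = _f0_hat(v)
        f1 = v.f1
        if f0 <= 0 or f1 == 0:
            return float(v.s_obs)
        mstar = m - n
        return float(v.s_obs + f0 * (1.0 - (1.0 - f1 / (n * f0 + f1)) ** mstar))
    if q == 1:
        return _hill_shannon_at_size(v, m)
    if q == 2:
        return _hill_simpson_at_size(v, m)
    raise ValueError("standardized estimation implemented for q in {0, 1, 2}")


def _bootstrap_community(v: AbundanceVector) -> np.ndarray:
    """Abundance-adjusted bootstrap community (observed + estimated unseen taxa)."""
    n, xi = v.n, v.x
    c_hat = estimate_coverage(v)
    f0 = int(math.ceil(_f0_hat(v)))
    phat = xi / n
    w = phat * (1.0 - phat) ** n
    lam = 0.0 if w.sum() == 0 else (1.0 - c_hat) / w.sum()
    p_seen = phat * (1.0 - lam * (1.0 - phat) ** n)
    if f0 > 0:
        p_unseen = np.full(f0, (1.0 - c_hat) / f0)
        probs = np.concatenate([p_seen, p_unseen])
    else:
        probs = p_seen
    total = probs.sum()
    return probs / total if total > 0 else probs


def estimate_at_coverage(
    x,
    target_c: float,
    q: float,
    n_boot: int = 200,
    seed: int | None = None,
    extrapolation_cap_factor: float = 2.0,
) -> DiversityEstimate:
    """Coverage-standardized Hill number with a percentile bootstrap CI.

    The sample size m* matching ``target_c`` is found by rarefaction below the
    reference size and analytic extrapolation above it; richness (q=0)
    extrapolation is capped at ``extrapolation_cap_factor * n`` (its reliability
    limit), while q=1 and q=2 extrapolate toward their asymptotes.  The CI
    resamples n individuals from the coverage-adjusted bootstrap community
    that includes an estimated unseen-taxon mass.
    """
    v = _as_vector(x)
    cap = int(extrapolation_cap_factor * v.n) if q == 0 else None
    m, basis = size_for_coverage(v, target_c, cap=cap)
    value = hill_at_size(v, m, q)
    est = DiversityEstimate(q=q, value=value, coverage_target=target_c, m=m, basis=basis)
    if n_boot and n_boot > 0:
        rng = np.random.default_rng(seed)
        probs = _bootstrap_community(v)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            counts = rng.multinomial(v.n, probs)
            vb = AbundanceVector(counts)
            try:
                mb, _ = size_for_coverage(vb, target_c, cap=None)
                mb = min(mb, cap) if cap is not None else mb
                reps[b] = hill_at_size(vb, mb, q)
            except UndefinedMetric:
                reps[b] = np.nan
        lo, hi = np.nanpercentile(reps, [2.5, 97.5])
        est.ci_low, est.ci_high = float(lo), float(hi)
    return est


def evenness(x, formula_id: str = "hill_ratio") -> float:
    """Evenness in [0, 1] from Hill numbers.

    ``hill_ratio``: (1D - 1)/(0D - 1); ``log_ratio``: ln(1D)/ln(0D).  Both are
    1 for perfectly even communities and fall toward 0 under dominance.
    """
    v = _as_vector(x)
    if v.s_obs < 2:
        raise UndefinedMetric("evenness undefined for fewer than two taxa")
    d0, d1 = hill_number(v, 0), hill_number(v, 1)
    return _evenness_from_hill(d0, d1, formula_id)


def _evenness_from_hill(d0: float, d1: float, formula_id: str) -> float:
    if d0 <= 1:
        raise UndefinedMetric("evenness undefined for fewer than two effective taxa")
    if formula_id == "hill_ratio":
        return float((d1 - 1.0) / (d0 - 1.0))
    if formula_id == "log_ratio":
        return float(math.log(d1) / math.log(d0))
    raise ValueError(f"unknown evenness formula: {formula_id!r}")


def shared_coverage_target(
    vectors: dict[str, AbundanceVector], cap_factor: float = 2.0
) -> float:
    """Default coverage policy: the minimum across samples of the coverage
    attainable at ``cap_factor`` times each reference sample size."""
    targets = [coverage_at_size(v, int(cap_factor * v.n)) for v in vectors.values() if v.n > 0]
    if not targets:
        raise UndefinedMetric("no non-empty samples in series")
    return float(min(targets))


def diversity_time_series(
    matrix: SiteYearMatrix,
    metrics: tuple[str, ...] = ("q0", "q1", "q2", "evenness"),
    grouping: str = "all",
    target_policy: str | float = "min_cmax",
    n_boot: int = 200,
    seed: int | None = None,
    evenness_formula: str = "hill_ratio",
) -> pd.DataFrame:
    """Coverage-standardized diversity estimates per site-year.

    All years are standardized to one common coverage target: either the
    policy ``"min_cmax"`` (minimum across years of the coverage reached at
    twice each year's sample size) or a fixed float target.  Evenness is
    derived from the standardized q0 and q1 values (and their paired bootstrap
    replicates).  Years with no individuals in the chosen group are reported
    as missing, never as zeros.
    """
    q_of = {"q0": 0, "q1": 1, "q2": 2}
    vectors = {}
    for year in matrix.years:
        arr = matrix.abundances(year, group=grouping)
        vectors[year] = AbundanceVector(arr)
    nonempty = {y: v for y, v in vectors.items() if v.n > 0}
    if not nonempty:
        raise UndefinedMetric("all site-years empty for the requested group")
    target = (
        shared_coverage_target(nonempty)
        if target_policy == "min_cmax"
        else float(target_policy)
    )

    rows = []
    ss = np.random.SeedSequence(seed)
    for year, v in vectors.items():
        year_seeds = ss.spawn(1)[0]
        if v.n == 0:
            for metric in metrics:
                rows.append(
                    dict(year=year, group=grouping, metric=metric, estimate=np.nan,
                         ci_low=np.nan, ci_high=np.nan, coverage=target, m=np.nan,
                         basis="missing")
                )
            continue
        child = np.random.default_rng(year_seeds)
        needs_even = "evenness" in metrics
        wanted_q = sorted({q_of[m] for m in metrics if m in q_of} | ({0, 1} if needs_even else set()))
        ests: dict[int, DiversityEstimate] = {}
        boot_reps: dict[int, np.ndarray] = {}
        probs = _bootstrap_community(v)
        boot_counts = (
            [child.multinomial(v.n, probs) for _ in range(n_boot)] if n_boot else []
        )
        for q in wanted_q:
            cap = 2 * v.n if q == 0 else None
            try:
                m, basis = size_for_coverage(v, target, cap=cap)
            except UndefinedMetric:
                m, basis = 2 * v.n, "extrapolated"  # q=0 capped at its limit
            ests[q] = DiversityEstimate(
                q=q, value=hill_at_size(v, m, q), coverage_target=target, m=m, basis=basis
            )
            reps = np.empty(len(boot_counts))
            for b, counts in enumerate(boot_counts):
                vb = AbundanceVector(counts)
                try:
                    mb, _ = size_for_coverage(vb, target, cap=None)
                    mb = min(mb, cap) if cap is not None else mb
                    reps[b] = hill_at_size(vb, mb, q)
                except UndefinedMetric:
                    reps[b] = np.nan
            boot_reps[q] = reps
        for metric in metrics:
            if metric in q_of:
                q = q_of[metric]
                e = ests[q]
                if len(boot_counts):
                    lo, hi = np.nanpercentile(boot_reps[q], [2.5, 97.5])
                else:
                    lo = hi = np.nan
                rows.append(
                    dict(year=year, group=grouping, metric=metric, estimate=e.value,
                         ci_low=lo, ci_high=hi, coverage=target, m=e.m, basis=e.basis)
                )
            elif metric == "evenness":
                try:
                    val = _evenness_from_hill(ests[0].value, ests[1].value, evenness_formula)
                except UndefinedMetric:
                    val = np.nan
                if len(boot_counts):
                    with np.errstate(all="ignore"):
                        er = (boot_reps[1] - 1.0) / (boot_reps[0] - 1.0)
                        if evenness_formula == "log_ratio":
                            er = np.log(boot_reps[1]) / np.log(boot_reps[0])
                    lo, hi = np.nanpercentile(er, [2.5, 97.5])
                else:
                    lo = hi = np.nan
                rows.append(
                    dict(year=year, group=grouping, metric=metric, estimate=val,
                         ci_low=lo, ci_high=hi, coverage=target, m=ests[1].m,
                         basis=ests[1].basis)
                )
            else:
                raise ValueError(f"unknown metric: {metric!r}")
    return pd.DataFrame(rows)
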