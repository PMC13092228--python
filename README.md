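# rockyshore

Statistical machinery for detecting and attributing biodiversity change in
long-term rocky intertidal monitoring, built around the Hewatt–Sagarin
transect at Hopkins Marine Station (Pacific Grove, California): a strip of 19
square-yard quadrats first censused in 1931–1933 and resurveyed 17 times
between 1993 and 2023 by a succession of investigator teams.  The package is
for ecologists working with multi-investigator resurvey data who need to
separate real community change from observer effects and unequal sampling
effort.

## What it computes

**Coverage-standardized Hill diversity.**  Diversity of order *q* is the Hill
number ᵠD — the effective number of equally abundant taxa — with ⁰D observed
richness, ¹D = exp(−Σ pᵢ ln pᵢ) (Hill-Shannon, "common" taxa), and
²D = 1/Σ pᵢ² (Hill-Simpson, "dominant" taxa), plus the evenness ratio
E = (¹D − 1)/(⁰D − 1).  Because the number of individuals per census varies
enormously, every estimate is standardized to a common sample coverage
Ĉ = 1 − (f₁/n)·[(n−1)f₁ / ((n−1)f₁ + 2f₂)] via exact hypergeometric
rarefaction below the reference sample size and the standard asymptotic
extrapolations above it, with a percentile bootstrap for uncertainty.

**Bayesian trend and attribution models.**  Four Normal-likelihood models are
fit by MCMC (4 chains, rank-normalized split R̂ < 1.05 and bulk ESS > 1000
required):

1. *trend + era*: y = α_era + β_year·year_c + ε, the total effect of time
   with investigator-era intercepts (year in centered decades);
2. *temperature, linear adjustment*: adds β_temp·t_c, where t is the 90th
   percentile of daily sea-surface temperature over the 365 days before each
   survey; conditioning on year blocks the backdoor path from unmeasured
   drivers that covary with time (a deliberately confounded naive variant
   regresses on temperature alone);
3. *temperature, Gaussian-process adjustment*: replaces the linear year term
   with a latent f(year) ~ GP(0, η² exp(−d²/ℓ²)), absorbing smooth non-linear
   and autocorrelated confounds (f is marginalized analytically);
4. *range-class contrast with measurement error*: per-taxon mean log change
   obsᵢ ~ Normal(θᵢ, seᵢ), θᵢ ~ Normal(α_class, σ_θ), reporting
   Δ = α_southern − α_coastwide.

**Evidence grading and baseline tests.**  Results are phrased in a language
of evidence: sign probabilities ≥ 0.95/0.90/0.80 grade a slope as
strong/moderate/weak; non-overlapping 95% (80%) credible intervals are strong
(weak) evidence of a difference; and change since the 1930s is declared
strong when no recent-year 95% posterior-predictive interval envelopes the
historical baseline value.

**Population change.**  Per-taxon log response ratios
LRR = ln[(n_year + 1)/(n_baseline + 1)] against the pooled 1931–1933 census,
an inclusion filter (≥ 20 individuals and ≥ 5 plots dataset-wide), and
geographic range classes split at Cape Mendocino (40.44° N) and Point
Conception (34.45° N).

**Synthetic surveys.**  A generator reproduces the statistical structure of
the survey — lognormal species-abundance distribution, range-class-dependent
trends, temperature acting on dominance, era- and mobility-specific detection
effort, taxonomy quirks (synonyms, qualitative scores, genus-level lumping) —
with exact bookkeeping, so the whole pipeline is testable without the
archived field data.

## Worked example

```python
import numpy as np
from rockyshore import datasets, evidence, inference, survey_data, synthetic_data
from rockyshore.diversity import diversity_time_series

# the published 48-taxon summary table for the transect
table = datasets.load_transect_summary()
counts = evidence.count_strong_changes(table)
print("taxa:", len(table), "| range classes:",
      {k: int(v) for k, v in table["range_class"].value_counts().items()})
print("strong declines / increases (strict CI convention):",
      counts["strict"]["n_declines"], "/", counts["strict"]["n_increases"])

# a synthetic survey through the full pipeline
config = synthetic_data.SimConfig()
records, truth = synthetic_data.generate_community(config, seed=42)
filtered, report = survey_data.apply_quantitative_filters(records, truth.crosswalk)
matrix = survey_data.pool_site_year_matrix(filtered)
print("site-years x taxa:", matrix.counts.shape, "| individuals:", matrix.total())

series = diversity_time_series(matrix, metrics=("q1",), n_boot=0)
recent = series[series["year"] != "1931-1933"]
data = inference.TrendData(
    year=recent["year"].astype(int),
    era=[survey_data.era_of_year(int(y)) for y in recent["year"]],
    y=recent["estimate"],
)
fit = inference.fit_trend_era_model(data)
beta = fit.draws("beta_year")
p_neg = evidence.prob_of_sign(beta, "negative")
print(f"Hill-Shannon trend: {np.median(beta):.2f} taxa per decade "
      f"(95% CI {np.quantile(beta, 0.025):.2f} to {np.quantile(beta, 0.975):.2f})")
print(f"P(decline) = {p_neg:.3f} -> {evidence.classify_slope_evidence(p_neg)} evidence")
```

prints

```
taxa: 48 | range classes: {'coastwide': 37, 'southern': 9, 'uncertain': 2}
strong declines / increases (strict CI convention): 20 / 21
site-years x taxa: (18, 120) | individuals: 23684
Hill-Shannon trend: -3.21 taxa per decade (95% CI -6.07 to -0.31)
P(decline) = 0.984 -> strong evidence
```

The first two lines recount the published per-taxon table: 48 common taxa, 37
coastwide / 9 southern / 2 of uncertain range, 20 of them with a 95% CI for
the log response ratio entirely below zero.  The rest runs a simulated survey
(18 site-years, 19 quadrats) through filtering, pooling, coverage
standardization, and the trend + era model; the simulated community was
generated with declining coastwide taxa, so the fitted Hill-Shannon slope is
negative with strong evidence.  A console script exposes the same stages
(`rockyshore simulate | ingest | diversity | sst | fit | evidence | lrr | run`).

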