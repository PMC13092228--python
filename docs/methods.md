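# Methods

This note documents the statistical choices in `rockyshore`: the estimators,
the models and their priors, the sampler, the synthetic-data generator, and
the places where the design was genuinely open.

## Data model and filtering

Raw survey records carry one taxon observation per (era, year, quadrat):
either a non-negative integer count or a qualitative code
(abundant/common/occasional/rare) — never both.  Five investigator eras are
analyzed (1931–1933 baseline, 1993–1996, 1999–2015, 2016–2019, 2020–2023);
the 1949 partial resurvey covered only 3 of the 19 core quadrats and is
rejected at load time with a warning.

Recorded names are mapped through a crosswalk to currently accepted analysis
names (many-to-one; harmonization can only reduce the number of distinct
taxa).  Four ordered filters then prepare the data for count-based analysis:

1. taxa never counted anywhere (qualitative-only) are dropped;
2. epibiont-flagged taxa (limpets riding on trochid shells, not assessed in
   the baseline) are dropped;
3. records identified above genus are dropped;
4. genus-level records are dropped when two or more species of that genus
   were also counted, to avoid double-counting richness.  The congener check
   is evaluated dataset-wide by default (configurable to per-era): the
   ambiguity a genus record creates does not respect era boundaries.

Taxa first quantified after the baseline are treated as true zeros in the
baseline if they were absent from the baseline investigator's full species
list, and as presence-only (excluded from count-based metrics, retained in a
registry) if the list recorded them without numbers — counts that were never
made cannot enter count-based estimators.  Filtering is idempotent, and the
report gives records and individuals removed per step in order.

Counts are pooled over the 19 core quadrats to site-year totals; the
baseline is pooled under a single "1931-1933" label because the historical
census was a single unreplicated effort.  Duplicate (site-year, quadrat,
taxon) rows are a hard error unless explicitly summed, since silent
summation hides double data entry.  Densities divide by 19 × 0.8361 m² (the
quadrats are historical square yards); eras with a single site-year report
no SD rather than zero.

## Diversity estimation

Hill numbers ᵠD for q = 0, 1, 2 are computed from relative abundances; the
generic form (Σ pᵢᵠ)^(1/(1−q)) is continuous through q = 1 and is exposed for
the continuity check.  Sample coverage uses the singleton/doubleton
estimator Ĉ = 1 − (f₁/n)·[(n−1)f₁/((n−1)f₁ + 2f₂)].

Standardization to a target coverage finds the sample size m\* whose expected
coverage reaches the target.  Below the reference size n: exact
hypergeometric rarefaction (log-gamma arithmetic; for q = 1 the expected
subsample entropy Σₖ −(k/m)ln(k/m)·Σᵢ P[Xᵢ = k]; for q = 2 the closed form
1/[1/m + (1−1/m)Σxᵢ(xᵢ−1)/(n(n−1))], valid at any m).  Above n: richness
extrapolates through the bias-corrected Chao estimate of undetected taxa and
is capped at 2n — beyond twice the reference size the extrapolation is
guesswork — while q = 1 (via the asymptotic entropy estimator, mixed in
proportion n/(n+m\*)) and q = 2 may approach their asymptotes.  When f₂ = 0
the usual substitution (f₁ − 1)/2 keeps the extrapolation defined; a target
beyond what the cap allows raises with advice to lower it.

The default series-wide coverage target is the minimum, across site-years,
of the coverage attained at twice each year's sample size — the standard
convention for coverage-based comparison — and is configurable to a fixed
value.  Uncertainty comes from a 200-replicate percentile bootstrap that
resamples n individuals from the coverage-adjusted community including an
estimated unseen-taxon mass, re-solving for m\* per replicate.  Evenness
(default (¹D−1)/(⁰D−1); ln ¹D/ln ⁰D selectable) is derived from the
standardized ⁰D and ¹D and their paired bootstrap replicates.  The
literature offers several evenness definitions; the `formula_id` switch
exists because no single one is canonical.  Undefined quantities (empty
samples, S < 2) propagate as missing values, never zeros.

## Temperature covariate

The attribution covariate is the empirical 90th percentile (linear
interpolation between order statistics, recorded in the output metadata) of
daily SST over the 365-day window ending the day before the year's first
survey; when the survey day is unknown, the prior calendar year is used.
The window precedes the survey so the hypothesized cause precedes the
effect.  Windows with fewer than 200 observed days yield a missing covariate
with a warning rather than an exception — a percentile over a sparse
hand-collected series misleads.  Window bounds and day counts are reported
so the choice is auditable.

## Models and priors

All four models use Normal likelihoods.  Year is centered and expressed in
decades, so slopes read directly as "per decade"; temperature is centered.
Eras are coded as indices (no reference level), one intercept each.

Priors are weakly informative and scale with the data:
α ~ Normal(ȳ, 2·sd(y)); β_year ~ Normal(0, 2·sd(y)) per decade;
β_temp ~ Normal(0, 2·sd(y)/sd(t)); σ ~ Exponential(1/sd(y)).  The GP
amplitude has η ~ half-Normal(0, sd(y)) and the length-scale ℓ a lognormal
prior centered at 8 years with log-SD 0.7, spanning roughly 2–30 years —
shorter would chase noise in an 18-point series, longer is indistinguishable
from a linear trend.  All are overridable, and a prior-predictive utility
simulates trend lines so the implied range can be inspected.

The GP model marginalizes the latent trend analytically:
y ~ MVN(α + β_temp·t_c, η²exp(−d²/ℓ²) + σ²I), with d the year distance and a
10⁻⁶ diagonal jitter (duplicate years are thereby handled); draws of f at
the observed years are reconstructed per posterior draw from the Gaussian
conditional.  Era intercepts are excluded from the GP model by default — the
latent trend can represent era-block shifts, and with 17 points the two are
not separable — but can be included.  The range-class model marginalizes the
per-taxon true means (obsᵢ ~ Normal(α_class, √(seᵢ² + σ_θ²))); SEs are
floored at 10⁻³ to avoid a degenerate likelihood.

## Sampling and diagnostics

Default protocol: 4 chains × 3000 iterations with 1500 warmup each (6000
retained draws); the GP model doubles both; the range-class model runs
2000/1000.  The default kernel is adaptive independence Metropolis–Hastings:
a Laplace approximation (BFGS mode plus finite-difference Hessian) whitens
the target; warmup runs a multivariate-t (df 10) proposal at the mode,
inflated 1.3×; the proposal is then moment-matched to the warmup draws and
fixed, so the retained chain is time-homogeneous.  These posteriors are
low-dimensional and nearly Gaussian, so acceptance is high and retained
draws are close to independent.  emcee's affine-invariant ensemble sampler
(differential-evolution moves on the same whitened target, post-warmup
sample thinned to the protocol's draw count) is available as an alternative
backend; the two are cross-checked against each other in the test suite.

Every fit attaches rank-normalized split R̂ and bulk ESS (ArviZ) per
parameter.  The pass rule is strict: R̂ < 1.05 and ESS > 1000 at the default
protocol; fits that fail are returned flagged, never silently accepted.
Replicate suites (below) run a reduced protocol of 4 × 1000/750 = 1000
retained draws with an ESS floor of 100, the scale at which hundreds of
fits stay affordable; replicates failing diagnostics are excluded and
counted in the reports.

Posterior predictions draw μ per year from the chains and add
Normal(0, σ) observation noise; the 95% predictive interval is forced to
envelope the 95% mean interval (a finite-draw guard).  The baseline envelope
test uses closed intervals — a baseline exactly on a bound counts as
contained, conservative toward "no change" — and reports the last containing
year so findings like "change after 1999" fall out directly.

Evidence grades are monotone step functions: sign probability ≥ 0.95/0.90/
0.80 → strong/moderate/weak; disjoint 95% (80%) credible intervals → strong
(weak).  CI-versus-zero counting always reports two conventions, because
printed tables round bounds to one decimal: strict (a bound equal to 0.0
touches zero) and rounded (such a bound is a rounded value of the interval's
sign; the degenerate (0, 0) interval counts as neither).

## Synthetic data

The generator inverts the analysis pipeline.  Per-taxon site-level expected
counts follow a lognormal SAD (meanlog 1.2, sdlog 1.8 — a long rare tail,
with many taxa near the detection limit, as in the real survey where the
taxon list far exceeds the per-year detected richness).  Range class drives
a log-linear trend per decade (+0.3 southern, −0.3 coastwide by default, so
southern taxa rise against the baseline and coastwide taxa fall), and the
prior-year SST p90 acts on the dominance structure by scaling the SAD spread
— warming concentrates abundance into dominants, depressing Hill-Shannon at
fixed richness, which makes the temperature effect a recoverable estimand.
Counts per quadrat are negative binomial (size 0.7) to emulate quadrat-scale
clumping.  The daily SST series is a seasonal sinusoid plus a 0.01 °C yr⁻¹
linear trend plus noise.

Detection effort is era- and mobility-specific, with one era (1999–2015)
undercounting mobile taxa.  Effort acts through two coupled mechanisms:
mild individual-level undercounting (binomial at effort^0.3, via the
binomial quantile at a fixed uniform) and species-level oversight — a
low-effort observer misses a sparse species outright with probability
(1 − effort)·exp(−site count/30).  Pure individual-level thinning was tried
first and rejected: coverage standardization is designed to undo it, and the
resulting mobile/sessile composition shift depresses Hill-Simpson more than
richness — the opposite of the observer artifact seen in real resurvey data,
where richness suffers because sparse taxa are overlooked wholesale.  Both
mechanisms use uniforms drawn independently of the effort values, so
lowering effort can never raise an observed count under a fixed seed (the
monotone-coupling property the tests rely on, and what makes the paired
with/without-artifact experiment exact).

Taxonomy quirks are injected at configurable rates and labelled in the
returned truth: historical synonyms in the early eras, qualitative-only
taxa, genus-level lumping in the last era (scored against the realized
records, since the filter only removes a genus record when two congeners
were actually counted), above-genus clades, and one epibiont taxon.  The
filter report is asserted to match the injected bookkeeping exactly.

What the generator does *not* emulate: spatial structure within and among
quadrats, tidal-height gradients, species interactions, temporal
autocorrelation in recruitment, and misidentification (as opposed to
synonymy).  Passing tests therefore show that the estimators and models
behave correctly under the assumed statistical structure — not that the
structure captures every feature of the field data.

## Calibration suites

Two replicate harnesses drive the headline checks, both at the reduced
sampler protocol:

* **Parameter recovery** — per replicate, data are simulated at the survey's
  own design (17 recent site-years in 4 eras; 20 taxa per range class with
  SE 0.1 for the contrast) with known β_year = −0.6 per decade,
  β_temp = −0.3 per °C, Δ = 2.0; each model is fit and scored for posterior-
  median bias and 95%-CI coverage.  100 replicates are used: a coverage
  proportion over 50 has a binomial spread wide enough to blur the
  0.90–0.98 window the check targets.
* **Confound signature** — the testable implication of the causal diagram:
  with a truly nil temperature effect and a smooth year-driven confound
  (with year also driving warming), the naive temperature-only model
  under-covers zero while the year-adjusted and GP models stay near nominal.

The GP's temperature coefficient shows a small attenuation (~0.08 at truth
−0.3) because the latent year trend absorbs part of any time-structured
temperature signal; this is inherent to GP confound adjustment, not a
sampler artifact (the emcee cross-check reproduces it).

## Known limitations

* Coverage standardization assumes individuals are sampled independently
  within a site-year; strong within-quadrat aggregation makes nominal
  bootstrap intervals somewhat optimistic.
* The q = 0 extrapolation cap (2n) means a series containing one very
  undersampled year can force all years to a lower common coverage than the
  well-sampled years could support.
* The independence-MH kernel relies on a decent Laplace approximation;
  strongly multimodal posteriors would show up as low acceptance and failed
  ESS checks rather than wrong answers, and the emcee backend is the
  fallback.
* A single site and a single temperature series: attribution rests on one
  time-series contrast, and no spatial replication can rescue it — the
  causal estimate is only as good as the assumed diagram.
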