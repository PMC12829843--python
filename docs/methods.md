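# Methods

## Lag decomposition

A species description's timeline is anchored by the resolved collection
dates of its type series and the publication date.  The three periods are
computed as calendar-day differences divided by 365.25 (a fixed year
length; the choice affects the third decimal at most):

* overall = publication − first collection,
* collection = last collection − first collection,
* description (*sensu stricto*) = publication − last collection,

so additivity `overall = collection + description` holds to floating-point
precision by construction.  Records whose publication date does not
strictly postdate the last resolved collection date are excluded at ingest
(reason `pub_before_collection`): negative lags are meaningless under
these definitions, and silently clamping them would bias the summaries.

### Imprecise dates

Verbatim date strings are parsed into an interval on the proleptic
Gregorian calendar (leap days honoured) and resolved to the **floor
midpoint**: the floor of the arithmetic mean of the first and last day of
the interval, so an even-length interval resolves to the earlier central
day ("February 2007" → 14 February).  Year-only strings resolve to
day-of-year 183 (2 July in a common year).  The precision class (`day`,
`day_range`, `month`, `year`) and interval span are preserved on every
event so downstream analyses can drop or down-weight low-precision dates.
Ambiguous all-numeric forms ("03/04/2010") are rejected rather than
guessed; ranges may cross month and year boundaries.

### Field trips

Unique resolved dates (same-day specimens deduplicated per species) are
segmented into trips: a gap of strictly more than `gap_days` (default 30)
between consecutive dates starts a new trip.  The rule is checked against
a brute-force connected-components oracle on exhaustive small instances.
Midpoint-resolved dates feed segmentation as if exact; the retained
precision classes let users audit trips containing coarse dates.

## Summary statistics

The per-group battery is: min, mean, SD (n−1), 10% trimmed mean
(dropping `floor(0.10·n)` values per side after sorting), median, MAD,
max, range, skewness, excess kurtosis, SE = SD/√n, and a 95% CI
half-width of 1.96·SE (normal-theory, not a t quantile — the 1.96
multiplier reproduces the reported interval arithmetic).  Skewness and
kurtosis implement the three classical estimator families (types 1–3 in
the Joanes–Gill taxonomy); the default is type 3, the convention of the
standard R descriptive routines.  MAD defaults to the normal-consistent
scaled variant (×1.4826), matching the same upstream convention; the raw
median-of-absolute-deviations is available via `mad_scale=1`.  Groups
with fewer than two values are emitted with statistics marked NaN rather
than dropped.

## Mixed models

The response is log description time in years.  Fixed effects: genetics
(0/1), author count, type-series size, species per paper, field-trip
count, genus richness — left unscaled by default (a z-scaling switch
exists for conditioning).  Random intercepts: genus and region, crossed,
in the global model; genus only in regional models (region covariates
constant within a region are dropped with a logged notice).  Before
fitting, numeric covariate pairs with |Pearson r| > 0.70 are flagged.

Estimation is **maximum likelihood, not REML**, because the null-model
comparison (likelihood ratio and AIC) requires likelihoods comparable
across fixed-effect structures.  The deviance is profiled: with variance
ratios γ_f = σ²_f/σ², β̂ and σ̂² have closed forms and only the γ are
optimised (log scale, bounded quasi-Newton, deviance tolerance ~1e-8,
multiple starts).  All linear algebra runs through the q×q capacitance
matrix `I_q + Γ^{1/2} Z'Z Γ^{1/2}` (q = total random-effect levels), so a
fit at n ≈ 900 takes milliseconds and large simulation studies are cheap.
Variance ratios below 1e-8 are pinned to exact zeros.  Non-convergence is
flagged on the returned fit with a warning, never a silent success.

Per-term inference uses Type-II Wald chi-square tests (each term's
columns tested jointly; with the default all-single-column terms this is
(coef/se)² on 1 df).  Standard errors treat the variance parameters as
known — the usual Wald convention for these models — which is mildly
anticonservative for covariates that vary only between clusters (e.g.
genus richness); the calibration study below quantifies the effect.

### Residual diagnostics

The fitted model is simulated `n_sim` times (default 250), drawing new
random-effect and residual deviates.  Because observations sharing a
random-effect draw are dependent, observed and simulated deviations are
first whitened by the Cholesky factor of the estimated marginal
covariance; each whitened coordinate's scaled residual is then its
randomized rank among the simulations (randomized PIT, which is exactly
Uniform(0,1) under a correct model — a deterministic mid-rank variant is
discrete and makes the KS test over-reject).  Three tests are reported:
Kolmogorov–Smirnov uniformity; dispersion, locating the observed residual
variance in the simulated-variance distribution (two-sided empirical p,
exchangeability-exact); and an outlier count (observations outside the
whole simulated envelope, binomial p with success probability
2/(n_sim+1)).  Identical seed and data give bit-identical results.

## Temporal trends

Variables are aggregated to one value per publication year within a scope
(global or one region): means over species for lags, author counts,
type-series sizes and trip counts; counts for species and (distinct)
papers; per-paper means over distinct papers; a percentage for genetics
use.  Years with no described species are absent, not zero-filled.

Each series is fitted two ways: OLS on year, and a cubic B-spline GAM
(basis dimension min(8, n−1)) with the smoothing weight chosen by
generalized cross-validation over a log-spaced grid.  The GCV score uses
an effective-degrees-of-freedom inflation factor of 1.4, the standard
corrective for GCV's tendency to undersmooth short series; without it the
selection-inflated null rejection rate of the chosen trend p-value was
measured at 17% (α = 0.05, 24-point series), versus 12% with it.  The
method with the larger unadjusted R² is selected, ties going to the
linear model; the reported p is the LM slope p or the GAM smooth-term p
(both serialized).  LOESS (degree 2, tricube weights, span 0.75) is
provided for presentation only.

## Synthetic data generator

The generator produces datasets with exactly the structure the inference
assumes, so estimator calibration can be tested against known truth.

* **Scale**: regional sample sizes 208 (Ecuador), 204 (India), 215
  (Madagascar), 269 (Melanesia) — 896 species — with 15 genera per
  region, genus sizes lognormal, species assigned to genera
  proportionally to richness.
* **Description lag**: `log(description_y) = β0 + Xβ + u_genus +
  v_region + ε`, with defaults β0 = 1.7, β = (genetics +0.15, authors
  −0.05, types 0, species/paper +0.04, trips −0.08, richness −0.001),
  σ²_genus = 0.20, σ²_region = 0.05, σ²_resid = 0.50 — chosen once so the
  generated global summaries sit at the observed order of magnitude
  (median overall ≈ 7 y, strongly right-skewed); they are emulation
  constants, not estimates.
* **Collection history**: trip count 1 + geometric with single-trip
  probability 0.531; inter-trip gaps 30 + buffer + lognormal days;
  within-trip gaps uniform below 30 − buffer.  The buffer (default 3 d)
  keeps every true gap strictly away from the segmentation threshold on
  both sides, so the pipeline recovers true trip counts exactly.
* **Covariates**: authors 1 + Poisson with a year-increasing rate
  (≈2.5 → ≈5 over the window); genetics Bernoulli with a logistic-in-year
  probability (≈0.15 → ≈0.95, midpoint 2010); types 1 + Poisson(7);
  species are partitioned into papers within (region, year), the paper
  size becoming the per-species covariate.
* **Dates**: the first collection date takes a seasonal month (wet-season
  peaked weights for Madagascar and India, even for Ecuador and
  Melanesia) and is anchored so the publication year hits a uniform draw
  from 2000–2023.  Masking degrades day-precision strings to imprecise
  dialects; the default masks 8% of events to the symmetric day-range
  form, which preserves midpoints exactly (month/year masking, which can
  shift midpoints by up to 15/183 days, is opt-in, and the masking log
  reports the worst-case shift per event for tolerance-aware checks).
* **Seeding**: hierarchical streams (one per species) make output
  reproducible and leave earlier species unchanged when the dataset
  grows.

### What the generator does not emulate

Real type series share one publication date per paper; generated species
in the same paper share the paper-size covariate and target year but keep
individual publication dates.  Genus effects are independent across
regions (no shared taxonomy), there is no phylogenetic or spatial
structure, no month/year date imprecision by default, and lag laws are
lognormal rather than estimated from data.  Passing calibration tests on
this generator therefore demonstrates correctness of the estimators under
the model's own assumptions — not that real description lags follow these
laws.

## Calibration study sizes

The test suite's simulation studies use: 200 replicates at n = 896 for
fixed-effect recovery and CI coverage (bias within 2 Monte-Carlo SEs per
coefficient; coverage pooled over the six slope coefficients, since
per-coefficient coverage at 200 replicates carries Monte-Carlo noise
comparable to the acceptance band); 1,000 replicates at n = 300 for the
Wald type-I error under the global null, pooled across terms; 200
replicates each for residual-diagnostic calibration and dispersion power
(doubled residual SD) at n = 300; and 300 i.i.d.-noise series for the
trend-selection error measurement.

## Known limitations

* Wald inference ignores variance-parameter uncertainty; between-cluster
  covariates can be slightly undercovered (observed ≈ 0.90–0.95 per
  coefficient at 15 genera/region).
* The region variance component is estimated from four levels and is
  reported as-is; its point estimate is very noisy.
* GAM smooth-term p-values after GCV selection remain approximate; model
  selection by R² inflates the chosen p-value's type-I error (measured
  ≈ 0.12 at α = 0.05) — trend p-values should be read with that in mind.
* The date parser accepts day-month-year and ISO dialects only; purely
  numeric day/month forms are rejected by design.
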