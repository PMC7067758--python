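# Methods

This note records the statistical model, the conventions adopted where the
underlying procedures are ambiguous, what the synthetic generator does and
does not emulate, and the numerical choices that matter.

## The nested variance model

For one trait, observations are modelled on the natural-log scale as

    y = mu + a_g + b_s(g) + e,
    a_g ~ N(0, s2_group),  b_s ~ N(0, s2_species),  e ~ N(0, s2_within),

with species nested in functional groups (deciduous shrub, evergreen
shrub, graminoid, forb). The residual is interpreted as within-species
variation; it also absorbs measurement error, which the data cannot
separate. Components are estimated by REML with the likelihood profiled
over mu and s2_within, leaving a two-dimensional bounded problem in the
variance ratios (s2_group/s2_within, s2_species/s2_within). Because the
random effects are nested, the marginal covariance is block diagonal by
group and each block inverts analytically via two rank-one Woodbury
updates, so one criterion evaluation costs O(n); the analytic gradient is
supplied to L-BFGS-B, with a Nelder-Mead polish only if the KKT conditions
are not met at the returned point. On balanced designs the interior REML
optimum coincides with the classical expected-mean-squares (nested ANOVA)
estimator; the test suite verifies agreement to < 1e-6 and cross-checks an
unbalanced fit against statsmodels MixedLM.

Conventions:

* Analysis scale is log by default (traits are treated as log-normal);
  a natural-scale toggle exists.
* "Greater than three observations per trait per species" for the per-site
  decomposition is read literally as >= 4, configurable to >= 3. The scan
  stage's own filter (>= 3 species with >= 2 observations each) is a
  separate, configurable eligibility rule; a site is eligible when enough
  *adequately sampled* species are present (species below the observation
  floor do not count toward the species minimum, but their records are not
  discarded).
* Degenerate inputs return a flagged decomposition instead of failing: one
  species -> all variance to the residual; all-singleton species -> the
  residual is unidentifiable and all variance is among species; both carry
  `converged=False`.
* Across-site summaries are unweighted means of per-site fractions.
* The model family is Gaussian on (log) values with identity link; no other
  link is implemented.

## Error-risk cleaning

Error risk of x in group G is |x − mean(G∖x)| / sd, with sd computed on
G∖x by default (consistent with the excluded mean; a flag restores the
include-x reading). The difference is absolute, so low-side unit errors
(e.g. mg recorded as g) are caught symmetrically. Zero-spread groups give
risk 0 if x equals the common value, +inf otherwise; groups smaller than 3
are skipped and logged.

The ladder runs strictly in order — (1) record vs whole trait
distribution, threshold 8.0; (2) dataset-level species means (species in
>= 4 datasets, threshold 3.0) else genus means (threshold 3.5), removing
the whole offending dataset × species (or × genus) cell, since the flagged
unit is the dataset mean; (3) record vs species, threshold interpolated
linearly from 2.25 at < 10 records to 4.0 at > 30 — each step on the
survivors of the previous one. Species with exactly 4 records are left
untouched (the rule is stated for "more than four"). Dataset-level means
are computed on the natural scale by default (toggle provided). The
global step pools all observations of a trait across species. Cleaning is
deliberately not idempotent (groups shrink), so the audited invariants are
that the report reconciles exactly with the removals and that every
removed record exceeded its step threshold.

With ~t-distributed reference statistics, the dataset-mean rule implicitly
assumes well-sampled species span many datasets; its false-flag rate under
the null is the two-sided tail of roughly sqrt(k/(k−1))·t_{k−2} at the
threshold, where k is the number of dataset means. At the default study
conditions (40 datasets) this contributes most of the ~2 % of clean
records removed — the price of a screen that reliably catches whole
mis-unit datasets.

## Synthetic generator

The generator emulates the statistical skeleton of a multi-contributor
trait compilation: six traits, log-normal, with per-trait variance
components calibrated so the planted biome-scale fractions sit near
group 0.26 / species 0.51 / within 0.23 and within-species CVs near 30 % —
values chosen to be realistic for widely measured vascular-plant traits.
Species effects carry a two-factor structure (size axis loading plant
height, leaf area, seed mass; economics axis loading LMA, LDMC and,
negatively, leaf nitrogen) plus an independent residual and a
habitat-filtering term shared by species whose home sites fall in the same
cluster. The habitat term is what makes local communities more similar
than random species subsets, and hence what produces the rise of the
within-species fraction at local scale that the scan detects; without it,
a random subset of species has the same expected among-species variance
as the full pool and no scale pattern exists. Sites sit in clusters on
one parallel (centres separated by at least the configured inter-cluster
distance, scatter bounded by half the cluster radius); species occupy
sites with probability exp(−turnover_rate · distance from home). Outliers
multiply natural-scale values by 50 (unit-error emulation); duplicates are
verbatim copies within the same dataset.

Defaults give ≈ 20,000 records from 90 species at 24 sites across 40
datasets. Dataset labels are assigned per record, mimicking well-sampled
species spanning dozens of contributors; with few datasets the
dataset-mean rule becomes a heavy-tailed low-df statistic and flags
aggressively — that is a property of the rule, not of the implementation.

Not emulated: real units and their heterogeneity, taxonomic synonymy,
gap-filled traits, non-random sampling effort, spatially structured
within-species variation, and correlated measurement error. Passing tests
therefore show the machinery is correct under the planted model, not that
any particular real-data conclusion holds.

## Geographic-scale scan

Scale of a step is the great-circle distance (haversine, sphere radius
6371.0 km) from the scan's start site to the farthest included site;
richness is the number of distinct species with measurements in the
included set. Sites are added by distance from the start site (not from
the growing set; a flagged alternative was considered and not needed),
ties broken lexicographically by site id. Per-step decompositions pool
all included records into one fit. "Among species" is f_group +
f_species — everything that is not residual — so within + among = 1 at
every step.

Binned summaries use half-open bins [k·w, (k+1)·w) with empirical 2.5/97.5
percentiles; bins with fewer than 3 steps are flagged interval-undefined.
The 10-bin significance test uses equal-width bins on the log10 axis
(log10(x + 1 km) for the geographic axis, which starts at 0; plain log10
for richness) and an OLS of fraction on a within/among indicator within
each bin — algebraically the pooled two-sample t test, which the suite
verifies. Bins with < 2 steps or no variance are flagged untestable.

## Breakpoint fits

The one-breakpoint model y = a + b1·x + b2·(x − psi)+ is continuous at
psi. Estimation is a grid search over interior x-quantiles followed by
iterative linearization (the gamma/b2 update), clamped to the interior
x-range, tolerance 1e-10, max 50 iterations; deterministic given the
input. Data with no detectable slope change (|b2| negligible) or a break
escaping the interior return `converged=False` with the best fit found;
the RSS then matches a simple line. Uncertainty is by case-resampling
bootstrap percentiles; resamples with fewer than 4 distinct x are
redrawn. Fits are run on step-level values (not bin means).

## Trait space

Species-mean log traits (mean of logs = log of geometric mean), complete
cases only; PCA on the correlation matrix (centred, unit-scaled — traits
have incommensurate units) via SVD. Axis signs are arbitrary, so each
axis is oriented with its largest-magnitude loading positive; explained
fractions sum to 1 and per-axis contributions to 100 by construction.
Subset comparisons (e.g. the climate-extreme species pool) reuse the
fitted global axes — subset scores are rows of the global score matrix.
The SSD→LDMC conversion is a log-log least-squares fit to caller-supplied
calibration pairs, reported with r, and is never used in the main
pipeline.

## Derived classifications

The biome pool is the union of the survey species list and species with a
record at a site with mean annual temperature < 0 °C. The climate-extreme
subset takes species with a record north of 66.5° N or at a MAT < 0 °C
site. Temperature classes use the unweighted mean of the class
temperature over a species' unique georeferenced sites with strict
thresholds: < −1 °C cold, > +1 °C warm, otherwise mid (boundary values are
mid). Records without coordinates are kept for cleaning and variance
stages but excluded from spatial and climate operations; the class
temperature is an explicit input column, deliberately not bound to a
specific climatology layer.

## Problem sizes and determinism

The bundled demo configuration (30 species, 12 sites, 5 obs per
species-site) runs the full pipeline in a few seconds; the analysis
scripts use the full defaults (≈ 20k records, 24-site scan). The
multi-seed studies use 50 databases for cleaning recovery, 50 balanced
draws for fraction recovery, 100 replicates × 100 bootstrap resamples for
breakpoint coverage, and 20 seeded scans on a 15-site / 40-species
configuration for the scale contrast — sizes chosen so the whole battery
completes in minutes on one CPU while keeping Monte-Carlo error well
inside the tested margins. Every stage is seed-deterministic; reruns with
the same seed and config produce identical outputs and manifests (up to
the timestamp).

## Known limitations

* Only one-way nesting (group/species) is supported; crossed effects
  (e.g. site × species) are out of scope, and per-site fits treat sites
  independently.
* The dataset-mean cleaning rule is low-powered and heavy-tailed when a
  species spans few datasets; counts per cell are not modelled.
* Variance partitioning is trait-by-trait and ignores cross-trait
  covariance.
* The REML implementation assumes Gaussian (log) responses; no GLMM
  families.
* The scan refits from scratch at every step; cost grows quadratically in
  site count (fine for tens of sites, not thousands).
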