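# traitvar

Sources of plant trait variation, from plot to biome scale.

Trait-based ecology leans on two assumptions: that most trait variation
occurs **among** species rather than within them, and that species traits
co-vary along a few axes (plant size; resource economics). Testing either
on compiled trait databases (TRY-style multi-contributor collections)
requires machinery that is easy to get wrong: duplicate and unit-error
screening that must not clip true extremes, nested variance decomposition,
and scale-dependent summaries. `traitvar` implements that machinery as a
tested library plus a reproducible analysis pipeline, exercised end to end
on a synthetic trait-database generator with known ground truth.

## What it computes

* **Error-risk cleaning** — for an observation *x* and reference group *G*,
  the error risk is |x − mean(G∖x)| / sd(G∖x). A three-step ladder screens
  each record against its whole trait distribution (risk > 8), dataset-level
  species/genus means against the other datasets' means (risk > 3.0 / 3.5),
  and each record against its species, with a sample-size-dependent
  threshold rising from 2.25 (< 10 records) to 4.0 (> 30 records). A
  duplicate-ratio rule collapses repeated (species, trait, value) triples in
  datasets where more than 30 % of records are copies.
* **Nested variance partitioning** — an intercept-only Gaussian mixed model
  y = μ + a_group + b_species(group) + e on log values, fitted by REML
  (profiled over the two variance ratios with closed-form block inversions);
  the residual variance is read as within-species variation. Fractions
  f_group + f_species + f_within = 1.
* **Geographic-scale scan** — from every eligible site, sites are added in
  order of great-circle distance and the pooled records re-partitioned at
  each step; step fractions are binned (5 km / 1 species) with empirical
  95 % intervals, tested for a within-vs-among difference in 10 equal bins,
  and summarised by one-breakpoint segmented fits.
* **Trait space** — PCA (correlation form) of species-mean log traits with
  loadings, explained variance, and per-axis trait contributions
  100·loading²/Σloading².
* **Synthetic generator** — log-normal traits with planted group / species /
  within variance components, a two-factor cross-trait covariance (size,
  economics), clustered sites with distance-decaying species turnover,
  injected 50× outliers and exact duplicates — so every stage can be scored
  against ground truth.

## Worked example

```bash
python analysis/01_generate_database.py
python analysis/02_clean_database.py
python analysis/03_partition_variance.py
```

prints (abridged):

```
generated 19632 records, 90 species, 24 sites
injected 398 outliers (2.0%) and 384 duplicates

19632 -> 18832 records (4.1% removed)
removals by step: {'dataset': 616, 'global': 91, 'species': 93}
outlier recall: 0.982

mean fractions: group=0.330 species=0.446 within=0.224
```

Read: the cleaning ladder recovered 98 % of the injected 50× outliers; the
nested decomposition attributes ~22 % of log-trait variance to
within-species differences, matching the planted 0.23 (the functional-group
share is noisy per trait — only four groups — exactly why it is reported
with the species share as a combined "among-species" fraction at the scan
stage). `analysis/04_scan_scales.py` and `analysis/05_trait_space.py`
continue with the scale scan (binned fractions, significance boxes,
breakpoints) and the PCA (first two axes ≈ 72 % of variance here).

The same stages are scriptable via the CLI:

```bash
traitvar run --seed 1 --outdir out/        # full pipeline + manifest
traitvar clean --in records.csv --out cleaned.csv --report report.csv
```

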