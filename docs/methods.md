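# Methods

This note documents the statistical models implemented in `methepi`, the
synthetic-data generator the tests run against, and the numerical and
design choices made where more than one reasonable option existed. It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Study design being modelled

The pipeline targets a two-arm-less ("everyone treated") clinical-trial
design: each subject has triglycerides (TG) measured at two pre-treatment
visits and two post-treatment visits, genome-scale DNA methylation (beta
values in (0,1)) measured once before and once after treatment, a GWAS
panel from which two candidate genes are extracted, and standard
covariates (average pre-treatment TG, age, centre, current smoking, sex).
Family structure present in the motivating cohort is deliberately
ignored: all models are ordinary least squares on unrelated-subject
assumptions, matching the analysis the pipeline reproduces.

## Phenotype

Drug response is `y = ln(mean(tg3, tg4) / mean(tg1, tg2))`. The log is
natural; since `y` only ever enters as a regression response, the base is
immaterial up to scale. Missing visits (never both in a block, by design
and by validated invariant) are singly imputed before averaging: within
each block, the two directed regressions (`tg2 ~ tg1`, `tg1 ~ tg2`, and
likewise post) are fit by OLS on complete-pair subjects and the missing
visit is predicted from its observed partner. Four separate directed
models — rather than one pooled model per block — is the simplest
construction consistent with the high within-block correlations the
design assumes; imputation is deterministic, idempotent, and never
touches observed values. At least 3 complete pairs per block are required
to fit a line; fewer raises an explicit error. No uncertainty is
propagated (single imputation is intentional; multiple imputation is out
of scope).

## Differential methylation

Per CpG site, the per-subject difference `d = β_post − β_pre` is tested
with a one-sample *t*-test: `t = mean(d)/(sd(d)/√n)`, `n−1` df,
two-sided. Testing is on raw beta differences by default; a logit-scale
(M-value) variant is available via `logit=True`. Zero-variance sites are
flagged degenerate and assigned `p = 1`: they carry no evidence and must
never pass a filter. The family-wise filter is Bonferroni, `α/m` over the
`m` tested sites, computed at full precision (display rounding is a
presentation concern). Betas are clamped to `[10⁻⁶, 1 − 10⁻⁶]` at
container construction so logits and log ratios stay finite.

A note on printed thresholds: `0.05/463 995 = 1.0776 × 10⁻⁷` (printed
elsewhere as 1.08 × 10⁻⁷ at 3 s.f.). For the second-stage association
family the analogous computation at 212 018 hypotheses gives
`2.36 × 10⁻⁷`; a widely circulated figure of `2.36 × 10⁻⁶` for that
family appears to carry a transcribed exponent, so this package always
computes `α/m` exactly rather than accepting a printed cutoff.

## Per-CpG association

For sites passing the first filter (two-stage design), the phenotype is
regressed on the site's methylation log ratio `r = ln(β_post/β_pre)` with
an intercept and *no* covariates — a deliberately minimal single-predictor
model; a covariate-adjusted variant (projecting both `y` and `r` off the
covariate span) exists behind a flag but is off by default. Slopes,
standard errors and two-sided `t` p-values (`n−2` df) come from the
closed-form simple-OLS solution, vectorised across sites.
Constant-predictor sites are degenerate (`p = 1`); perfect fits report a
p-value at the floating-point floor rather than 0. Output is
Manhattan-ready (sorted by chromosome and position with `−log10 p`).

## Over-representation analysis

The signal gene list is the union (hence deduplicated) of gene symbols
annotated to sites that passed the differential-methylation filter and
have association `p ≤ p_cut` (default 0.05); CpGs may map to 0, 1 or 2+
genes, and unannotated sites are skipped with a logged count. Each
category of a gene-set database is tested one-sided for
over-representation with the hypergeometric upper tail: with universe
size `N`, category size `K = C`, drawn list size `n` (after intersecting
with the universe) and observed overlap `O`, `raw_p = P(X ≥ O)`,
`E = nK/N`, `R = O/E`. The reference universe per database is the union
of its category members intersected with the annotation's gene universe —
standard ORA practice and the only construction computable from supplied
files (web-service universes are not reproducible, which is why absolute
ORA p-values from such services cannot be compared directly). Adjustment
is Benjamini–Hochberg by default, Bonferroni optionally; depletion is not
tested. Results sort by raw p ascending with ties broken by category id.

## Cross-gene epistasis scan

For every pair with one SNP in each candidate gene (within-gene pairs are
never formed), two nested Gaussian models are compared:

```
base:  y ~ 1 + covariates + gA + gB
full:  y ~ 1 + covariates + gA + gB + gA·gB
```

with additive 0/1/2 dosage coding and a single product interaction
(1 df). A 4-df categorical-interaction variant was considered and not
made the default: the additive×additive product is the field-standard
first test and matches dosage-coded inputs. The statistic is the Gaussian
likelihood ratio `λ = n·ln(RSS_base/RSS_full)` referred to χ²₁ — an LRT
rather than the partial *F*; both are monotone in the RSS ratio and their
p-values agree asymptotically (verified in the suite at n = 2000, 99% of
null pairs within 0.002).

Implementation: all pairs share one QR decomposition of the covariate
design; phenotype, dosage and product columns are residualised once and
each pair reduces to a 2- vs 3-column regression (Frisch–Waugh–Lovell),
which reproduces the naive per-pair RSS values exactly (asserted against
statsmodels in the tests) while keeping a 340-pair scan under 0.1 s.
Monomorphic SNPs yield skipped-pair records; an interaction column
collinear with the base design (relative residual norm ≤ 10⁻⁹) yields a
degenerate record with `p = 1`; tiny negative RSS improvements from
roundoff are clamped to zero. The scan requires inputs to pass
`completeness_filter` (drop SNPs with any missing dosage among scan
samples, drop monomorphic SNPs), after which no per-pair missing-data
handling is needed. Significance is `p ≤ α/m` with `m` the cross-gene
pair count; genomic coordinates are 1-based throughout.

Covariates default to the fixed list (average pre-treatment TG, age,
centre as indicator contrasts, smoking, sex). Screening candidate
covariates by marginal significance at α = 0.05 is available as an
optional pre-step, but the fixed list is the default for determinism.

## Synthetic cohorts

The generator (`methepi.simulate`) emulates the study conditions; its
defaults are fixed once and are the conditions under which all replicated
validation results are computed.

* **Scale**: 680 subjects; 10⁴ CpG sites by default (chosen so a full
  pipeline run is interactive; the n_cpgs field accepts the full
  463 995-site scale).
* **TG visits** are generated on the log scale (positivity for free):
  subject level `b ~ N(ln 110, 0.20)`, plus per-visit noise with variance
  `V_e = V_s(1−ρ)/ρ`, so the within-block correlation equals the target —
  0.90 pre, 0.91 post by default. The post-block shared level is
  `b + y_signal`, carrying the planted genetic signal into the panel so
  the phenotype module recovers it. Missingness (default 5% per visit)
  removes at most one visit per block, preserving the design invariant.
* **Methylation**: per site, a latent subject logit level (site mean
  `N(0, 1.3)`, subject scatter `U(0.2, 0.6)`); pre and post measurements
  add independent `N(0, 0.1)` logit noise to that shared level, so under
  no shift the two visits are exchangeable and the paired-test null is
  exact. A fraction (default 0.45, mirroring the motivating analysis's
  ≈ 0.457 passing fraction) of sites receives a post-treatment logit
  shift of ±0.3, which at n = 680 pushes essentially every shifted site
  past the Bonferroni cutoff, so the passing fraction approaches the
  shifted fraction from below. Methylation is independent of the
  phenotype by default (consistent with an association stage that finds
  no genome-wide-significant site); consequently the curated gene list is
  effectively random and the ORA stage acts as a negative control unless
  the planted-enrichment pathway is exercised directly.
* **Genotypes**: per SNP i.i.d. `Binomial(2, MAF)` (Hardy–Weinberg), no
  within-gene LD by default. Gene A carries 68 SNPs: the four published
  FTO MAFs (0.34, 0.41, 0.29, 0.12) plus an even grid on [0.05, 0.5];
  gene B carries 5: the three published ALKBH5 MAFs (0.18, 0.45, 0.24)
  plus 0.30 and 0.38.
* **Phenotype**: `y = covariate effects + β_int·(gA−ḡA)(gB−ḡB) +
  N(0, σ)`, planted on the first SNP of each gene (MAF 0.34 × 0.18).
  Centring makes the product uncorrelated with each dosage under
  cross-gene independence, so marginal additive effects vanish by
  construction — the generator's whole point: interactions detectable in
  the absence of main effects. Defaults σ = 0.2 (log-ratio units,
  matching a realistic drug-response spread) and β_int = 0.14, fixed by a
  power pilot as the smallest round value at which the planted pair tops
  the scan and clears Bonferroni in ≈ all of 200 replicates while both
  marginal tests stay non-significant; at β_int = 0.12 joint power was a
  marginal ≈ 0.91.
* **Annotation/gene sets**: CpGs map to 0/1/2 genes (10/70/20%),
  categories are random gene subsets; one planted category draws 80% of
  its members from a designated signal-gene pool so the ORA pathway can
  be validated end to end. The truth record lists shifted CpGs, the
  interacting pair and its coefficient, the signal genes and the planted
  category.

All randomness descends from a single seed via `numpy.random.SeedSequence`
spawning; identical configs produce byte-identical serialized cohorts.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: genomic autocorrelation of methylation,
cell-type composition, within-gene LD (an AR(1) dosage-correlation option
was considered and left out of the default), family relatedness,
non-Gaussian phenotype tails, and batch effects. Operating
characteristics measured here are for the idealised design.

## Validation approach

Every statistical engine has an independent oracle in the test suite:
paired *t* against scipy's paired test and the closed-form formula, OLS
slopes against covariance ratios and statsmodels, the LRT against
explicit nested statsmodels fits, the hypergeometric tail against
exhaustive enumeration of all draws for every universe N ≤ 12 (exact,
rational arithmetic). Operating characteristics are measured by
replication: family-wise error of the null scan over 500 cohorts (bounded
by α, checked against the 99% Monte-Carlo band), and planted-pair
power/marginal suppression over 200 cohorts. `scripts/acceptance.py`
recomputes all of these from scratch.

## Numerical choices

* Beta clamp 10⁻⁶; collinearity tolerance 10⁻⁹ (relative residual norm);
  RSS ratios clamped at 1 from below before the log.
* Degenerate results are never NaN: `p = 1` with an explicit flag/status.
* p-values are serialized in scientific notation at 6 significant
  figures; all tabular output is TSV (UTF-8, Unix newlines — gene
  aliases may contain commas), with canonical column orders so repeated
  runs are byte-identical.
* VCF import converts GT to minor-allele dosage with the minor allele
  defined by in-sample frequency, ties broken toward ALT; multi-allelic
  records are skipped with a counted warning.

## Known limitations

* The LRT uses the χ²₁ reference; at small n it is slightly liberal
  relative to the partial *F* (the suite quantifies the gap).
* The paired *t* on raw beta differences relies on approximate normality
  of differences; the logit-scale option is preferable near the beta
  boundaries.
* ORA p-values depend on the reference universe; only ratios and relative
  rankings are comparable across differently-universed analyses.
* The pipeline has no relatedness correction; applying it to family data
  will inflate type-I error.
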