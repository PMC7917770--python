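# Methods

This note documents the statistical models behind `susceptigene`, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical conventions that matter for reproducing
results.

## The screen

**Stage 1 — dependency.** Per gene, the arithmetic mean of the CRISPR
dependency score is taken separately over the target-type cell lines and
over all other lines (missing scores excluded; a minimum observation count,
default 1 per group, gates eligibility). A gene is selected when
`mean_target < thr_target` **and** `mean_other > thr_other`, with strict
inequalities so boundary genes are excluded ("below −0.5", "higher than
−0.2" read literally). Defaults −0.5 / −0.2. `summary="median"` is
available but the default is the mean, the plain reading of "average".

**Stage 2 — expression.** Fold change is computed on the linear TPM scale
as `(mean_tumor + c) / (mean_reference + c)` with pseudocount `c = 1`; a
`scale="log2"` dialect (difference of mean `log2(TPM + c)`, reported as
`2**diff`) is provided because expression portals typically work on
log-transformed TPM and the convention used upstream of fold-change tables
is often unstated. Both thresholds (fold > 3, mean tumor TPM > 10) are
strict.

**Stage 3 — survival.** Samples are split at the q and 1−q expression
quantiles (default q = 0.25, the "25% highest and lowest" design; q = 0.5
gives a median split covering everyone). Cuts are inclusive — samples tied
with the quantile value join the extreme group — for determinism; when
heavy ties collapse both cuts, tied samples go to the low group with a
warning. The hazard ratio is a univariate Cox proportional-hazards fit on
the high/low indicator: Newton–Raphson on the Breslow partial likelihood,
covariate centered, steps clipped to ±5, convergence at |Δβ| < 1e−8 within
50 iterations, 95% CI from the observed information. Monotone likelihoods
(e.g. all events in one group) are returned flagged with an infinite bound,
never raised, so a screen over many genes continues. Breslow is the default
tie handling because the independent oracle used in the tests
(scikit-survival) implements it exactly; with continuous simulated times
Breslow and Efron coincide. The log-rank test accumulates, at each distinct
event time, observed minus hypergeometric-expected events with the usual
variance term, χ² with 1 df.

**Funnel.** Stages are strictly nested (each stage scores only the previous
stage's passers), mirroring the screen design; `nested=False` scores every
gene at every stage for exploratory use. The final candidate rule —
stage 1 + stage 2 passes, HR > 1, log-rank p < 0.05 — is this package's
explicit default; the source screen design ranks genes by HR without a
printed cut, so the cut is configuration, not dogma.

## Regulatory layer

Intervals are BED-convention: 0-based, half-open, strand-agnostic overlap
with a ≥ 1 bp threshold; abutting intervals do not overlap. Peak
classification partitions peaks exactly into promoter/non-promoter sets.
Venn overlap is peak-level and reported from both set perspectives, because
interval overlap is many-to-many and a single count would hide the
asymmetry. Genomic distribution assigns each peak to the
highest-precedence overlapping category (promoter > exon > intron >
intergenic by default) and compares against each category's share of
annotated base pairs (merged intervals). Promoter-signal ranking
aggregates, per gene, the signal of peaks overlapping any of its promoters
— `max` by default ("highest promoter level"), `sum` optional — sorted
descending with ties broken by gene id.

## Differential expression

Size factors are raw median-of-ratios: for genes with nonzero counts in all
samples, the median of count over per-gene geometric mean. A
`rescale="median"` option divides by the median factor so that a majority
of unscaled samples sit at exactly 1; the raw factors are the default
because they are what the estimator defines. The test is deliberately
simple: normalize, `log2(x+1)`, Welch two-sample t per gene; the package is
not a negative-binomial GLM engine, and the module accepts externally
computed (fold, p) tables so the DE *filter* — |fold| ≥ 2 (inclusive) and
p < 0.01 (strict), no multiplicity correction by default, BH optional — can
be applied to any upstream engine. The Welch stand-in is mildly
conservative on NB counts at 4 vs 4 replicates (measured null type-I
≈ 0.006–0.008 at p < 0.01), which the calibration tests pin to the
[0.005, 0.02] band.

## Preranked enrichment

The enrichment score is the classic weighted running sum: hits advance by
`|metric|^p` normalized over the set's hits (p = 1 default, p = 0 gives the
unweighted KS-like statistic), misses retreat by `1/(N − N_hits)`; ES is
the signed extremum, and the leading edge is the hit prefix (positive ES)
or suffix (negative ES). Significance uses gene-label permutation (random
same-size sets), appropriate for a preranked list where no phenotype
columns exist to permute. `nominal_p = (1 + #{same-sign |null| ≥ |ES|}) /
(1 + #{same-sign null})` and `NES = ES / mean(|same-sign null|)`. Two
consequences worth knowing: the attainable p floor is ≈ 2/n_perm (the
same-sign null is about half the permutations), and NES is sign-stratified,
so positive and negative scores are normalized against different null
magnitudes. Permutations are seeded; identical seed gives identical
results. Ties in the metric are broken by stable input order.

## Synthetic data

One global seed expands into fixed per-generator substreams
(`SeedSequence(seed, spawn_key=(k,))`), so generating one dataset never
perturbs another. All generators are bit-reproducible given the config.

* **Dependency**: background scores Normal(0, 0.15) — dependency scores of
  non-essential genes sit near zero with modest spread; planted essential
  genes shift their target-line scores by −1.0.
* **Expression**: log-normal TPM, per-gene baseline median log-normal
  around 5 TPM; planted overexpressed genes sit in the well-expressed range
  (reference median ≈ 20 TPM with mild spread) and have tumor samples
  multiplied by the planted fold (default 8).
* **Survival**: exponential event times (baseline hazard 0.005 per time
  unit), cohort of 300 tumor samples, Uniform(0, τ) censoring with τ solved
  so the expected censored fraction matches the configured rate (default
  0.2). Hazard is multiplied by `exp(log_hr)` (default log 2.5) for the top
  quartile of a latent per-sample risk factor on which the planted
  prognostic genes load. At the default loading of 1.0 the planted genes
  are perfectly co-ranked with the factor, so each one realizes the
  configured hazard ratio exactly between its own expression quartiles —
  the generator's contract. Lower loadings attenuate the realized per-gene
  HR roughly as the quartile misclassification they induce, and exist for
  sensitivity analyses. The perfectly co-ranked default also means all
  planted genes share identical high/low groups, hence identical fitted
  HRs within one simulation; real prognostic signatures are only
  imperfectly correlated, so passing tests here demonstrate estimator
  correctness, not robustness to signature heterogeneity.
* **Counts**: negative-binomial with dispersion α = 0.1
  (Var = μ + αμ²), baseline means log-normal around 100, 4 replicates per
  condition; α = 0 gives Poisson, and a `noiseless` mode emits rounded
  means for degenerate-limit tests.
* **Genome**: two chromosomes (1.2 Mb + 0.8 Mb), 200 non-overlapping 2 kb
  promoters placed on jittered slots and owned by a *random* subset of the
  gene universe (so promoter ownership is independent of every planted
  set), 1000 peaks of 200 bp placed to overlap a promoter with probability
  0.3 and to avoid promoters otherwise, log-normal signal.

What the generators do **not** emulate: real dependency-score correlation
structure across lineages, heavy-tailed TPM outliers and batch effects,
non-proportional hazards, over-dispersion trends (dispersion–mean
relationships), peak width/signal correlation, or sequence content. Tests
passing on these simulations validate the estimators and the pipeline
plumbing under the stated models, not performance on any real dataset.

## Numerical conventions

* Survival times must be strictly positive; event indicators are 0/1.
* KM with zero events is the constant curve 1; log-rank with zero total
  variance returns χ² = 0, p = 1; p-values are floored at the smallest
  positive float rather than 0.
* Welch test with zero variance in both groups: p = 1 when the means agree,
  the smallest positive float when they differ.
* All TSV writers use `float_format="%.10g"`, which makes repeated runs of
  the same configuration byte-identical.
* Threshold comparisons follow the stated strict/inclusive conventions
  exactly; every filter is monotone in its thresholds and covered by
  property tests.

## Problem sizes

The test suite and `scripts/acceptance.py` use simulation sizes chosen to
give tight Monte-Carlo error at interactive runtimes: 2,000-gene universes
with 30 planted genes over 10–20 seeds for end-to-end recovery, 1,000
replicates of n = 500 cohorts for Cox recovery and coverage, 10,000 null NB
genes for DE calibration, and 300–500 random sets at 200–500 permutations
for GSEA calibration. These sizes put binomial standard errors well inside
the asserted bands; scaling them up changes nothing but the error bars.

## Known limitations

* The Cox model is univariate with a binary covariate; no multivariate
  adjustment, proportionality diagnostics, or competing risks.
* The DE stand-in has no dispersion shrinkage and loses power relative to
  NB-GLM engines at low counts; it is a filter vehicle, not a DESeq2
  replacement.
* GSEA reports nominal p (optionally BH across sets); no cross-set FDR of
  the permutation-matched kind.
* Peak-level Venn counts are not base-pair Venn areas; the two perspectives
  can differ legitimately.
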