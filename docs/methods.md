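# Methods

## The problem

Tumor endothelial cells (TECs) whose Wnt/BCL9 signaling is intact build
extracellular matrix and support vessel formation; cells in which BCL9
function is lost shift toward ribosomal, proliferative and metabolic
programs.  Two 50-gene signatures summarize the contrast: the **True
list** (matrix-building program: collagens, SPARC, DCN, ...) and the
**False list** (perturbed program: ribosomal proteins, TOP2A, CCND1,
...).  The package scores any expression profile — one cell or one bulk
tumor — for the balance between the two programs and asks whether that
balance stratifies patient survival.

## Single-sample enrichment score

For gene *g* with expression *x\_g1 ... x\_gn* across the *n* samples of
a matrix, the kernel CDF transform is

&emsp; ẑ\_gj = (1/n) Σ\_k Φ((x\_gj − x\_gk)/h\_g),&emsp; h\_g = sd\_g/4,

with Φ the standard normal CDF.  It places each observation within the
gene's own cross-sample distribution on a common (0, 1) scale; as
h\_g → 0 it converges to the empirical CDF (a tested property).  A
zero-variance gene maps to 0.5 — the well-defined limit of the kernel
average.  Within each sample, genes are ranked by ẑ (rank 1 = largest);
ties break by gene identifier so results do not depend on row order or
floating-point platform quirks.

The enrichment score for a gene set of size *m* in a matrix of *G*
genes is a weighted rank random walk: stepping through genes from rank
1 to rank *G*, the walk rises by w\_g / Σ\_members w at each member gene
(w\_g = |r\_g − (G+1)/2|^τ, τ = 1 by default) and falls by 1/(G − m) at
each non-member.  With ν⁺ the walk's maximum above zero and ν⁻ its
minimum below zero, the default `gsva_diff` statistic is ν⁺ + ν⁻ and
`gsva_max` is the extreme of larger magnitude.  Both are bounded in
[−1, 1].  The degenerate configuration of a single member gene sitting
exactly at the central rank (odd *G*) has zero upward weight and is
rejected rather than silently scored.  A `mean_z` statistic (mean
per-gene z-score over set members) is provided as a structurally
unrelated cross-check; on planted-program simulations the two
rank-correlate above 0.8.

Gene symbols match case-insensitively (the signatures are
mouse-derived but are applied to human cohorts); unmatched symbols are
dropped and counted, and a set matching fewer than 80% of its symbols
(configurable) is flagged rather than rejected.  The transcribed
symbol `PDSSTN` matches no standard gene and simply never matches.

## The ratio score and its stability flags

Per sample,

&emsp; score = ES(True list) / (ES(False list) + 10⁻¹⁰).

The additive constant only prevents exact division by zero.  Because
enrichment scores are signed, the denominator can be negative or pass
near zero; the statistic is computed exactly as defined and each row
carries two diagnostics instead of any stabilization:

* `unstable` — |ES(False)| < 10⁻⁶: the ratio's magnitude is dominated
  by the guard constant;
* `sign_caution` — ES(False) < 0: the ratio's sign is inverted
  relative to the numerator.

**Known limitation.**  When one cell population is enriched for each
program, the two enrichment scores are almost perfectly
anti-correlated (ES(False) ≈ −ES(True)), so the ratio collapses toward
−1 in *both* populations and the remaining separation is noise-limited
and heavy-tailed.  On the package's own simulations the ratio
separates True-program from False-program cells with AUC ≈ 0.7 while
its numerator alone, or the difference ES(True) − ES(False), separate
with AUC ≈ 1.0.  The difference is available as
`score_cohort(..., method="difference")`, clearly labeled as a
robustness variant distinct from the published ratio; the ratio
remains the default.

## Deriving signature pairs

`derive_gene_lists` rebuilds a True/False pair from any labeled
two-group matrix by the classic signal-to-noise marker metric
(mean₁ − mean₂)/(sd₁ + sd₂), denominator floored at 10⁻⁸, taking the
top-k genes in each direction (k = 50 default, ties by gene
identifier).  Signal-to-noise was chosen as the derivation metric
because it is the canonical two-group ranking for signature
construction; the derivation is deliberately decoupled from the
built-in lists, which always drive the headline score.

## Survival stratification

* **Maxstat cut-point.**  Each sample receives the log-rank score
  a\_i = δ\_i − H(t\_i) (event indicator minus Nelson–Aalen cumulative
  hazard).  For every candidate cut-point *c* — a distinct observed
  score value with between 10% and 90% of samples above it — the
  linear statistic Σ\_{score>c} a\_i is standardized by its
  permutation mean and variance, and the *c* maximizing |T| is
  selected (ties toward the smallest candidate).  Because maximizing
  over candidates inflates the naive test, the p-value is a seeded
  permutation tail probability of max\_c |T| (default B = 1000, with
  add-one smoothing (b+1)/(B+1), so p ≥ 1/(B+1)).  Under a null
  cohort the test's empirical size at the 0.05 level is ≈ 0.04–0.05
  (tested at 500 replicates × 200 permutations).
* **Kaplan–Meier / log-rank.**  Standard product-limit estimate and
  the 1-df log-rank chi-square with hypergeometric variance; censored
  observations tied with an event time count as at risk (censoring
  after events).  Both are cross-checked against lifelines in the
  test suite.
* **Cox hazard ratio.**  One binary covariate ("high" = score strictly
  above the cut-point), Breslow tie handling, Newton iteration from
  β = 0 until |score function| < 10⁻⁸ (max 50 iterations), standard
  error from the observed information.  With no ties the score test
  at β = 0 equals the log-rank statistic (tested to 10⁻⁶).  |β| > 15
  is treated as complete separation — the partial likelihood is
  unbounded and the score function underflows — and reported as a
  signed infinite trend with `converged = False` rather than a number.
* No multiplicity correction is applied across cohorts; callers
  analyzing many groups should adjust downstream.

## Synthetic data

The generator plants exactly the structure the analysis assumes and
nothing more:

* Counts are negative-binomial with per-gene mean `baseline_mean`
  (default 5 for the single-cell generator, 20 for the bulk cohort)
  and shared size parameter θ (`nb_dispersion`, defaults 2 and 10;
  variance = μ + μ²/θ), multiplied by log-normal per-cell library-size
  factors with CV 0.2.  These defaults emulate droplet scRNA-seq
  overdispersion on a compact gene panel (≥ 200 genes so the two
  50-gene blocks leave background).
* The first 100 gene identifiers are the built-in True and False
  symbols, so symbol matching is exercised on the real code path.
  A population's program genes have mean multiplied by 2^lfc; in the
  cohort the high group shifts True up and False down by the same
  factor (low group mirrored).
* Event times are exponential with rate `baseline_rate` (low group)
  or `baseline_rate · planted_hr` (high group); censoring is an
  independent exponential, giving exact closed-form hazards so the
  planted HR is recovered without bias (median estimated HR over 50
  replicates at HR = 3, n = 300 falls in [2.4, 3.6]).
* Not emulated: doublets, ambient RNA, batch effects, cell-cycle
  structure, differentiation continua.  Passing tests therefore show
  the statistics behave correctly under their own assumptions, not
  that the signatures generalize to any particular real cohort.
* One integer seed per generator; composed stages split it through
  `numpy.random.SeedSequence`, so pipelines are bit-reproducible.

The expression scale the enrichment statistic is applied to (raw
counts vs library-size-normalized log counts) is left to the caller:
the kernel transform assumes continuous data, `normalize_log` provides
the standard normalization, and the CLI normalizes by default with a
`--no-normalize` escape hatch.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run entirely on generated
data at desk scale, chosen to make each statistical property
measurable with comfortable margin: 200-gene panels with 2 × 2000
cells for score separation, cohorts of 300 patients for hazard-ratio
recovery (50 replicates), and 500 replicates × 200 permutations for
the null calibration of the maxstat test.
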