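# endoscore

Gene-signature scoring of the tumor endothelial BCL9 program, with
survival stratification.

Tumor endothelial cells with intact Wnt/BCL9 signaling build
extracellular matrix and support angiogenesis; losing BCL9 function
pushes them toward ribosomal/proliferative programs.  `endoscore`
ships the two 50-gene signatures of these states (the **True** and
**False** lists), scores any expression matrix — single cells or bulk
tumors — for the balance between them, and tests whether the score
stratifies patient survival.  It is aimed at computational biologists
who want the full statistical path (enrichment scoring → cut-point
selection → survival contrast) as inspectable, tested code rather
than a chain of black-box calls.

## What it computes

For each sample *j*, each gene's expression is placed on a common
scale by a Gaussian-kernel CDF transform across samples,
ẑ\_gj = (1/n) Σ\_k Φ((x\_gj − x\_gk)/h\_g) with h\_g = sd\_g/4; genes
are ranked per sample and a weighted rank random walk yields a
single-sample enrichment score ES ∈ [−1, 1] for any gene set (the
GSVA family of statistics, implemented from first principles and
checked exhaustively against a brute-force oracle).  The per-sample
ratio score is

&emsp; **score = ES(True list) / (ES(False list) + 10⁻¹⁰)**

with diagnostic flags for near-zero or negative denominators (see
`docs/methods.md` for why those matter; a difference variant
ES(True) − ES(False) is available as a robustness option).

A scored cohort is split at the cut-point maximizing the standardized
log-rank statistic over all admissible thresholds (maximally selected
rank statistics), with a seeded permutation p-value that accounts for
the selection; the resulting high/low groups are compared by
Kaplan–Meier curves, the log-rank test, and a Cox
proportional-hazards hazard ratio (Breslow ties, Newton iteration).

A synthetic-data module generates negative-binomial single-cell-like
matrices with planted True/False programs and bulk cohorts with a
planted hazard ratio, so every stage is testable without downloads.

## Worked example

Simulate a 200-patient cohort in which a planted high-risk group
(hazard ratio 3) over-expresses the True program, score it, and
stratify:

```python
from endoscore import (SimCohortConfig, simulate_cohort, normalize_log,
                       score_cohort, stratify_and_analyze)

matrix, records, truth = simulate_cohort(
    SimCohortConfig(n_patients=200, planted_hr=3.0, expression_lfc=1.0, seed=42))
table = score_cohort(normalize_log(matrix), method="difference")
print(table.table.head(3).round(4))

report = stratify_and_analyze(table, records, n_permutations=1000, seed=42)
print(f"cutpoint      {report.maxstat.cutpoint:.4f}")
print(f"maxstat p     {report.maxstat.p_value:.4f}")
print(f"n high / low  {report.maxstat.n_high} / {report.maxstat.n_low}")
print(f"log-rank p    {report.logrank.p_value:.2e}")
print(f"hazard ratio  {report.cox.hr:.2f}  (Wald p {report.cox.p_value:.2e})")
```

prints

```
             es_true  es_false   score  unstable  sign_caution
sample_id
patient0000   0.5641   -0.6782  1.2423     False          True
patient0001   0.6506   -0.6315  1.2820     False          True
patient0002   0.5675   -0.5851  1.1526     False          True
cutpoint      -1.1866
maxstat p     0.0010
n high / low  103 / 97
log-rank p    1.74e-07
hazard ratio  2.46  (Wald p 3.76e-07)
```

Each patient's True-program enrichment (`es_true` ≈ +0.6 for high-risk
patients) and False-program enrichment (`es_false`, here negative, so
`sign_caution` marks the ratio's sign inversion) combine into the
score; the maxstat split is significant after accounting for
cut-point selection (permutation p = 0.001), and the high-score group
carries a 2.5-fold event hazard, close to the planted 3-fold.

The same pipeline runs from the shell:

```sh
endoscore run-all --seed 42 --n-perm 1000 --out results/
# results/sim/      matrix.mtx + genes.tsv + samples.tsv + survival.tsv
# results/scores/   scores.tsv   (sample_id, es_true, es_false, score, flags)
# results/report/   report.tsv   (cutpoint, p-values, HR, CI), km_curves.tsv
```

Re-running with the same seed reproduces every output byte for byte.

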