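"""The BCL9 endothelial function score.

Houses the two published 50-gene signatures — the "True" list, enriched
in endothelial/fibroblast cells with intact BCL9 function (extracellular
matrix construction, e.g. collagens, SPARC, DCN), and the "False" list,
enriched in BCL9-perturbed cells (ribosomal, proliferative and metabolic
programs) — and the per-sample ratio statistic built on them:

    score = ES(True list) / (ES(False list) + 1e-10)

where ES is a single-sample enrichment score (GSVA-style by default).
The tiny additive constant only guards exact division by zero; because
enrichment scores are signed, the denominator can still be negative or
near zero, so every score carries two diagnostic flags: ``unstable``
(|ES_false| below a threshold, the ratio's magnitude is guard-dominated)
and ``sign_caution`` (ES_false < 0, the ratio's sign is inverted
relative to the numerator).

Also provides ``derive_gene_lists``, which rebuilds such a True/False
pair from any labeled two-group expression matrix by signal-to-noise
marker ranking (top-k up in each direction).

The built-in lists are a verbatim transcription; the symbol ``PDSSTN``
matches no standard gene and simply never matches data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneListPair, GeneSet, ScoreTable
from .gsva import gsva_scores, mean_z_scores

__all__ = [
    "BCL9_TRUE_SYMBOLS",
    "BCL9_FALSE_SYMBOLS",
    "builtin_gene_lists",
    "bcl9_endo_score",
    "score_cohort",
    "derive_gene_lists",
]

EPSILON = 1e-10
INSTABILITY_THRESHOLD = 1e-6

# Intact-program ("True") signature: extracellular-matrix / vessel-wall genes.
BCL9_TRUE_SYMBOLS = (
    "IGFBP7", "SPARC", "RARRES2", "BGN", "LOXL1", "COL5A2", "FSTL1", "COL6A2",
    "DCN", "MFAP5", "SERPING1", "AEBP1", "GPX3", "THY1", "MMP2", "BMP1",
    "FBN1", "ADAMTS2", "COL1A1", "COL6A3", "RCN3", "FBLN2", "PLPP3", "LOXL2",
    "CD248", "COL6A1", "PDSSTN", "RNASE4", "COL3A1", "COL1A2", "COL5A3",
    "C1QTNF6", "MGST1", "SERPINF1", "SOD3", "EBF1", "EFEMP2", "CYGB", "SULF1",
    "FXYD1", "VCAN", "NBL1", "FN1", "TGFBR2", "SERPINA3", "SELENOM", "MMP14",
    "RCN1", "GPX7", "BICC1",
)

# Perturbed-program ("False") signature: ribosomal / proliferative genes.
BCL9_FALSE_SYMBOLS = (
    "TCP1", "RPL12", "RPL3", "RPL4", "TMPO", "RPL7", "PRKG2", "RRM2", "LARS2",
    "FCER1G", "RAD21", "EZR", "MTAP", "CD9", "RPS6", "TOP2A", "HSP90AB1",
    "HSPA9", "MT-CYB", "HBEGF", "AMIGO2", "ACTN4", "ACTB", "CAVIN2", "PLA2G7",
    "CENPF", "ATP5F1B", "HSPA8", "EEF2", "TUBA1C", "RPS18", "ANLN", "RAN",
    "WDR31", "NOLC1", "CPE", "TM4SF1", "HSPD1", "SPP1", "PHGDH", "TUBA1B",
    "S100A4", "CD74", "UBE2C", "LGALS7", "HMGB2", "CAV2", "ESM1", "CCND1",
    "HMGA1",
)


def builtin_gene_lists() -> GeneListPair:
    """The published True/False 50-gene signature pair, in printed order."""
    return GeneListPair(
        true_list=GeneSet("BCL9_true", BCL9_TRUE_SYMBOLS),
        false_list=GeneSet("BCL9_false", BCL9_FALSE_SYMBOLS),
    )


def bcl9_endo_score(es_true: float, es_false: float,
                    epsilon: float = EPSILON) -> tuple[float, bool, bool]:
    """The ratio score for one sample, with stability diagnostics.

    Returns ``(score, unstable, sign_caution)`` where
    ``score = es_true / (es_false + epsilon)``.
    """
    if not (np.isfinite(es_true) and np.isfinite(es_false)):
        raise ValueError("enrichment scores must be finite")
    denom = es_false + epsilon
    if denom == 0.0:
        raise ZeroDivisionError(
            f"denominator es_false + epsilon is exactly zero (es_false={es_false!r})"
        )
    score = es_true / denom
    unstable = abs(es_false) < INSTABILITY_THRESHOLD
    sign_caution = es_false < 0
    return float(score), bool(unstable), bool(sign_caution)


def score_cohort(matrix: ExpressionMatrix, lists: GeneListPair | None = None,
                 method: str = "gsva_diff", epsilon: float = EPSILON,
                 tau: float = 1.0, min_match_fraction: float = 0.8) -> ScoreTable:
    """Score every sample of a matrix with the True/False ratio statistic.

    ``method`` selects the enrichment statistic: ``gsva_diff`` (default),
    ``gsva_max`` or ``mean_z``.  ``method="difference"`` returns
    ``es_true - es_false`` instead of the ratio — a robustness variant
    that avoids the near-zero denominator, not the published statistic.
    """
    if lists is None:
        lists = builtin_gene_lists()
    sets = [lists.true_list, lists.false_list]
    es_method = "gsva_diff" if method == "difference" else method
    if es_method == "mean_z":
        es = mean_z_scores(matrix, sets, min_match_fraction=min_match_fraction)
    else:
        es = gsva_scores(matrix, sets, tau=tau, variant=es_method,
                         min_match_fraction=min_match_fraction)
    es_true = es.scores.loc[lists.true_list.name]
    es_false = es.scores.loc[lists.false_list.name]

    rows = []
    for sid in matrix.sample_ids:
        t, f = float(es_true[sid]), float(es_false[sid])
        if method == "difference":
            score, unstable, sign_caution = t - f, False, f < 0
        else:
            score, unstable, sign_caution = bcl9_endo_score(t, f, epsilon=epsilon)
        rows.append((sid, t, f, score, unstable, sign_caution))
    table = pd.DataFrame(rows, columns=["sample_id", "es_true", "es_false", "score",
                                        "unstable", "sign_caution"]).set_index("sample_id")
    return ScoreTable(table=table, method=method, epsilon=epsilon)


def derive_gene_lists(matrix: ExpressionMatrix, labels: np.ndarray, k: int = 50,
                      metric: str = "signal_to_noise",
                      names: tuple[str, str] = ("derived_true", "derived_false"),
                      ) -> GeneListPair:
    """Derive a True/False signature pair from a labeled two-group matrix.

    ``labels`` is a per-sample boolean vector (True-cluster membership).
    Per gene, signal-to-noise = (mean_T - mean_F) / (sd_T + sd_F) with the
    denominator floored at 1e-8; the True list is the top-``k`` genes by
    descending metric, the False list the top-``k`` by ascending.  Ties
    break by gene identifier.
    """
    if metric != "signal_to_noise":
        raise ValueError(f"unknown metric {metric!r}")
    labels = np.asarray(labels, dtype=bool)
    if labels.shape != (matrix.n_samples,):
        raise ValueError("labels length must equal number of samples")
    n_t = int(labels.sum())
    n_f = int((~labels).sum())
    if n_t < 3 or n_f < 3:
        raise ValueError(f"each group needs >= 3 samples (got {n_t} True, {n_f} False)")
    if 2 * k > matrix.n_genes:
        raise ValueError(f"k={k} too large for {matrix.n_genes} genes (need k <= genes/2)")

    xt = matrix.values[:, labels]
    xf = matrix.values[:, ~labels]
    denom = np.maximum(xt.std(axis=1, ddof=1) + xf.std(axis=1, ddof=1), 1e-8)
    s2n = (xt.mean(axis=1) - xf.mean(axis=1)) / denom

    id_order = np.argsort(np.argsort(np.asarray(matrix.gene_ids, dtype=object)))
    desc = np.lexsort((id_order, -s2n))  # descending metric, ties by gene ID
    asc = np.lexsort((id_order, s2n))
    genes = np.asarray(matrix.gene_ids, dtype=object)
    return GeneListPair(
        true_list=GeneSet(names[0], genes[desc[:k]]),
        false_list=GeneSet(names[1], genes[asc[:k]]),
    )
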