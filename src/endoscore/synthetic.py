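"""Synthetic expression and survival cohorts with planted structure.

Every downstream stage of the package — enrichment scoring, the ratio
score, cut-point stratification — is exercised on data from this module,
so its generative model deliberately mirrors the assumptions those
stages make:

* **Counts** are negative-binomial with a per-gene mean and a shared
  dispersion, the standard first-order emulation of droplet scRNA-seq
  counts.  Cell-to-cell depth variation enters as log-normal library
  size factors with configurable coefficient of variation.
* **Programs**: the first 50 genes carry the built-in True-list symbols
  and the next 50 the False-list symbols, so symbol matching runs on the
  same code path as real data.  A population's program genes have their
  mean multiplied by ``2**log2_fold_change``.
* **Survival** times are exponential: the planted hazard ratio between
  the high- and low-score groups is then exact, and independent
  exponential censoring yields right-censored records.

A single integer seed drives each generator; composed pipelines split it
through ``numpy.random.SeedSequence`` so stages are independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bcl9 import BCL9_FALSE_SYMBOLS, BCL9_TRUE_SYMBOLS
from .datatypes import ExpressionMatrix, SurvivalRecord

__all__ = [
    "SimPopulationSpec",
    "SimExpressionConfig",
    "SimCohortConfig",
    "SimTruth",
    "simulate_expression",
    "simulate_cohort",
    "normalize_log",
]

_PROGRAMS = ("true_program", "false_program", "none")
_BLOCK = 50  # genes per program block


@dataclass(frozen=True)
class SimPopulationSpec:
    """One simulated cell population.

    ``program`` names which gene block (if any) is shifted up by
    ``log2_fold_change`` in this population.
    """

    name: str
    n_cells: int
    program: str = "none"
    log2_fold_change: float = 0.0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError(f"population {self.name!r}: n_cells must be >= 1")
        if self.program not in _PROGRAMS:
            raise ValueError(f"population {self.name!r}: program must be one of {_PROGRAMS}")
        if not np.isfinite(self.log2_fold_change) or self.log2_fold_change < 0:
            raise ValueError(f"population {self.name!r}: log2_fold_change must be finite and >= 0")


@dataclass(frozen=True)
class SimExpressionConfig:
    """Single-cell-like count matrix configuration.

    ``baseline_mean`` is the negative-binomial mean of every gene before
    program shifts; ``nb_dispersion`` is the NB size parameter theta
    (variance = mu + mu^2/theta); ``library_size_cv`` the coefficient of
    variation of log-normal per-cell depth factors.
    """

    n_genes: int = 500
    populations: tuple[SimPopulationSpec, ...] = ()
    baseline_mean: float = 5.0
    nb_dispersion: float = 2.0
    library_size_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 4 * _BLOCK:
            raise ValueError(
                f"n_genes must be >= {4 * _BLOCK} so the two {_BLOCK}-gene program "
                f"blocks leave background genes (got {self.n_genes})")
        if not self.populations:
            raise ValueError("at least one population is required")
        if self.baseline_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("baseline_mean and nb_dispersion must be positive")
        if self.library_size_cv < 0:
            raise ValueError("library_size_cv must be >= 0")


@dataclass(frozen=True)
class SimCohortConfig:
    """Bulk cohort with a planted prognostic high/low contrast.

    High-group patients have True-program genes up-shifted and
    False-program genes down-shifted by ``expression_lfc`` (low group
    mirrored), and an event hazard ``baseline_rate * planted_hr`` versus
    ``baseline_rate`` for the low group.  Censoring is
    exponential(``censor_rate``).
    """

    n_patients: int = 300
    frac_high: float = 0.5
    planted_hr: float = 2.0
    baseline_rate: float = 0.1
    censor_rate: float = 0.05
    expression_lfc: float = 1.0
    seed: int = 0
    n_genes: int = 400
    baseline_mean: float = 20.0
    nb_dispersion: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.frac_high < 1:
            raise ValueError("frac_high must be in (0, 1)")
        n_high = round(self.frac_high * self.n_patients)
        if n_high < 2 or self.n_patients - n_high < 2:
            raise ValueError("each cohort group needs >= 2 patients")
        for name in ("planted_hr", "baseline_rate", "censor_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.expression_lfc < 0:
            raise ValueError("expression_lfc must be >= 0")
        if self.n_genes < 4 * _BLOCK:
            raise ValueError(f"n_genes must be >= {4 * _BLOCK}")


@dataclass
class SimTruth:
    """Ground truth of a simulation: per-sample labels and planted effects."""

    labels: dict[str, str]
    program_gene_ids: tuple[tuple[str, ...], tuple[str, ...]]
    planted_hr: float = 1.0


def _gene_panel(n_genes: int) -> list[str]:
    genes = list(BCL9_TRUE_SYMBOLS) + list(BCL9_FALSE_SYMBOLS)
    genes += [f"BG{i:05d}" for i in range(n_genes - 2 * _BLOCK)]
    return genes


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    # negative binomial with mean mu and size theta: p = theta / (theta + mu)
    return rng.negative_binomial(theta, theta / (theta + mean))


def simulate_expression(config: SimExpressionConfig) -> tuple[ExpressionMatrix, SimTruth]:
    """Simulate a single-cell-like count matrix with planted programs.

    Returns the gene-by-cell count matrix and the ground truth (cell ->
    population name, program gene identifiers).
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    genes = _gene_panel(config.n_genes)
    true_idx = np.arange(0, _BLOCK)
    false_idx = np.arange(_BLOCK, 2 * _BLOCK)

    columns, labels, sample_ids = [], {}, []
    cell = 0
    for pop in config.populations:
        mu = np.full(config.n_genes, config.baseline_mean)
        if pop.program == "true_program":
            mu[true_idx] *= 2.0 ** pop.log2_fold_change
        elif pop.program == "false_program":
            mu[false_idx] *= 2.0 ** pop.log2_fold_change
        if config.library_size_cv > 0:
            sigma2 = np.log1p(config.library_size_cv ** 2)
            size_factors = rng.lognormal(-sigma2 / 2, np.sqrt(sigma2), pop.n_cells)
        else:
            size_factors = np.ones(pop.n_cells)
        block = _nb_draw(rng, mu[:, None] * size_factors[None, :], config.nb_dispersion)
        columns.append(block)
        for _ in range(pop.n_cells):
            sid = f"cell{cell:06d}"
            sample_ids.append(sid)
            labels[sid] = pop.name
            cell += 1
    values = np.concatenate(columns, axis=1).astype(float)
    matrix = ExpressionMatrix(genes, sample_ids, values)
    truth = SimTruth(labels=labels,
                     program_gene_ids=(tuple(BCL9_TRUE_SYMBOLS), tuple(BCL9_FALSE_SYMBOLS)))
    return matrix, truth


def simulate_cohort(config: SimCohortConfig,
                    ) -> tuple[ExpressionMatrix, list[SurvivalRecord], SimTruth]:
    """Simulate a bulk cohort whose survival depends on a planted group.

    Returns the count matrix, right-censored survival records and the
    ground-truth labels ("high" / "low") with the planted hazard ratio.
    """
    seqs = np.random.SeedSequence(config.seed).spawn(2)
    rng_expr = np.random.default_rng(seqs[0])
    rng_surv = np.random.default_rng(seqs[1])

    n = config.n_patients
    n_high = round(config.frac_high * n)
    high = np.zeros(n, dtype=bool)
    high[:n_high] = True

    genes = _gene_panel(config.n_genes)
    sample_ids = [f"patient{i:04d}" for i in range(n)]
    shift = 2.0 ** config.expression_lfc
    mu = np.full((config.n_genes, n), config.baseline_mean)
    mu[0:_BLOCK, high] *= shift
    mu[0:_BLOCK, ~high] /= shift
    mu[_BLOCK:2 * _BLOCK, high] /= shift
    mu[_BLOCK:2 * _BLOCK, ~high] *= shift
    values = _nb_draw(rng_expr, mu, config.nb_dispersion).astype(float)
    matrix = ExpressionMatrix(genes, sample_ids, values)

    rate = np.where(high, config.baseline_rate * config.planted_hr, config.baseline_rate)
    event_time = rng_surv.exponential(1.0 / rate)
    censor_time = rng_surv.exponential(1.0 / config.censor_rate, size=n)
    observed = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    records = [SurvivalRecord(sid, float(ti), int(ei))
               for sid, ti, ei in zip(sample_ids, observed, event)]

    labels = {sid: ("high" if h else "low") for sid, h in zip(sample_ids, high)}
    truth = SimTruth(labels=labels,
                     program_gene_ids=(tuple(BCL9_TRUE_SYMBOLS), tuple(BCL9_FALSE_SYMBOLS)),
                     planted_hr=config.planted_hr)
    return matrix, records, truth


def normalize_log(matrix: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Depth-normalize each sample to total ``scale``, then log1p.

    The standard library-size normalization for count matrices; a sample
    with zero total counts is rejected by name.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    x = matrix.values
    if np.any(x < 0):
        raise ValueError("normalize_log expects non-negative counts")
    totals = x.sum(axis=0)
    zero = np.nonzero(totals == 0)[0]
    if len(zero):
        raise ValueError(f"sample {matrix.sample_ids[zero[0]]!r} has zero total counts")
    values = np.log1p(x / totals[None, :] * scale)
    return ExpressionMatrix(list(matrix.gene_ids), list(matrix.sample_ids), values)
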