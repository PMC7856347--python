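"""Core in-memory containers shared across the package.

The central object is :class:`ExpressionMatrix`, a dense gene-by-sample
matrix with unique string identifiers on both axes.  Gene sets are plain
named symbol lists; enrichment results and per-sample ratio scores are
thin dataclasses around pandas structures so they stay easy to write to
TSV and to assert on in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "GeneListPair",
    "EnrichmentScores",
    "ScoreTable",
    "SurvivalRecord",
]


def _check_unique(ids: Sequence[str], kind: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = pd.Index(ids)
        dupes = sorted(dupes[dupes.duplicated()].unique())
        raise ValueError(f"duplicate {kind} identifiers: {dupes[:5]}")
    return ids


@dataclass
class ExpressionMatrix:
    """Dense gene-by-sample expression matrix.

    Parameters
    ----------
    gene_ids
        Row identifiers, unique.
    sample_ids
        Column identifiers, unique.
    values
        Real matrix of shape ``(len(gene_ids), len(sample_ids))`` with all
        entries finite.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def gene_indexer(self) -> dict[str, int]:
        """Map upper-cased gene symbol -> row index (first occurrence wins)."""
        out: dict[str, int] = {}
        for i, g in enumerate(self.gene_ids):
            out.setdefault(g.upper(), i)
        return out


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene symbols.

    Symbols must be non-empty and unique after upper-casing; the original
    spelling and order are preserved.
    """

    name: str
    symbols: tuple[str, ...]

    def __init__(self, name: str, symbols: Iterable[str]):
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "symbols", tuple(str(s) for s in symbols))
        if not self.symbols:
            raise ValueError(f"gene set {self.name!r} is empty")
        upper = [s.upper() for s in self.symbols]
        if len(set(upper)) != len(upper):
            raise ValueError(f"gene set {self.name!r} has duplicate symbols after upper-casing")

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def upper_symbols(self) -> frozenset[str]:
        return frozenset(s.upper() for s in self.symbols)


@dataclass(frozen=True)
class GeneListPair:
    """A paired "True"/"False" signature: two disjoint gene sets.

    The True list marks the intact endothelial matrix-building program and
    the False list the perturbed program; their ratio defines the
    endothelial function score.
    """

    true_list: GeneSet
    false_list: GeneSet

    def __post_init__(self) -> None:
        overlap = self.true_list.upper_symbols & self.false_list.upper_symbols
        if overlap:
            raise ValueError(f"true and false lists overlap: {sorted(overlap)[:5]}")


@dataclass
class EnrichmentScores:
    """Per-sample enrichment scores for one or more gene sets.

    ``scores`` is a set-by-sample DataFrame; ``method`` tags the statistic
    (``gsva_diff``, ``gsva_max`` or ``mean_z``); ``matched_genes`` counts,
    per set, how many symbols matched matrix genes, and ``low_match_sets``
    flags sets that matched fewer than the requested fraction.
    """

    scores: pd.DataFrame  # set_names x sample_ids
    method: str
    matched_genes: dict[str, int]
    low_match_sets: frozenset[str] = field(default_factory=frozenset)


@dataclass
class ScoreTable:
    """Per-sample endothelial ratio scores with stability diagnostics.

    Columns: ``es_true``, ``es_false``, ``score``, ``unstable`` (the
    denominator magnitude is below the instability threshold, so the
    epsilon guard dominates) and ``sign_caution`` (the denominator is
    negative, so the ratio's sign is inverted relative to the numerator).
    """

    table: pd.DataFrame  # indexed by sample_id
    method: str
    epsilon: float

    REQUIRED_COLUMNS = ("es_true", "es_false", "score", "unstable", "sign_caution")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"score table missing columns {missing}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def scores(self) -> pd.Series:
        return self.table["score"]


@dataclass(frozen=True)
class SurvivalRecord:
    """One right-censored survival observation."""

    sample_id: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time <= 0:
            raise ValueError(f"sample {self.sample_id!r}: time must be positive, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"sample {self.sample_id!r}: event must be 0 or 1, got {self.event}")
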