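"""Readers and writers for the interchange formats.

Expression matrices travel either as MatrixMarket coordinate files with
``genes.tsv`` / ``samples.tsv`` sidecars (the de-facto single-cell
interchange layout) or as dense TSV with genes as rows.  Gene sets use
GMT; survival tables are TSV with columns ``sample_id  time  event``.
All pairs round-trip losslessly on valid data.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .datatypes import ExpressionMatrix, GeneSet, ScoreTable, SurvivalRecord

__all__ = [
    "write_expression_mtx",
    "write_expression_tsv",
    "read_expression",
    "read_gmt",
    "write_gmt",
    "read_survival_tsv",
    "write_survival_tsv",
    "write_score_table",
    "read_score_table",
]

logger = logging.getLogger(__name__)


def write_expression_mtx(matrix: ExpressionMatrix, directory: str | Path) -> Path:
    """Write matrix.mtx + genes.tsv + samples.tsv into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(directory / "matrix.mtx", sparse.coo_matrix(matrix.values))
    (directory / "genes.tsv").write_text("".join(f"{g}\n" for g in matrix.gene_ids))
    (directory / "samples.tsv").write_text("".join(f"{s}\n" for s in matrix.sample_ids))
    return directory / "matrix.mtx"


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> Path:
    path = Path(path)
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene_id")
    return path


def _read_sidecar(path: Path) -> list[str]:
    ids = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    # tolerate multi-column sidecars (id in the first column)
    return [line.split("\t")[0] for line in ids]


def read_expression(path: str | Path, fmt: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix from ``mtx`` or dense ``tsv`` format.

    ``fmt`` is inferred from the suffix when omitted.  MTX input expects
    ``genes.tsv`` and ``samples.tsv`` sidecars next to the matrix file.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix == ".mtx" or path.is_dir() else "tsv"
    if fmt == "mtx":
        mtx_path = path / "matrix.mtx" if path.is_dir() else path
        if not mtx_path.exists():
            raise FileNotFoundError(mtx_path)
        raw = spio.mmread(mtx_path)
        values = np.asarray(raw.todense() if sparse.issparse(raw) else raw, dtype=float)
        genes = _read_sidecar(mtx_path.parent / "genes.tsv")
        samples = _read_sidecar(mtx_path.parent / "samples.tsv")
        if values.shape != (len(genes), len(samples)):
            raise ValueError(
                f"matrix shape {values.shape} does not match sidecars "
                f"({len(genes)} genes, {len(samples)} samples)")
        return ExpressionMatrix(genes, samples, values)
    if fmt == "tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        if len(set(header)) != len(header):
            dupes = sorted({h for h in header if header.count(h) > 1})
            raise ValueError(f"duplicate sample identifiers in header: {dupes[:5]}")
        frame = pd.read_csv(path, sep="\t", index_col=0)
        for col in frame.columns:
            bad = frame[col][~frame[col].apply(lambda v: isinstance(v, (int, float, np.number)))]
            if len(bad):
                raise ValueError(f"non-numeric value in column {col!r}, "
                                 f"row {bad.index[0]!r}: {bad.iloc[0]!r}")
        if frame.isna().any().any():
            raise ValueError("expression TSV contains missing values")
        return ExpressionMatrix.from_frame(frame)
    raise ValueError(f"unknown expression format {fmt!r}")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: tab-separated name, description, symbols..."""
    path = Path(path)
    sets: list[GeneSet] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path.name} line {lineno}: expected >= 3 tab-separated "
                             f"fields (name, description, symbols...), got {len(fields)}")
        symbols = [s for s in fields[2:] if s]
        if not symbols:
            raise ValueError(f"{path.name} line {lineno}: gene set {fields[0]!r} has no symbols")
        sets.append(GeneSet(fields[0], symbols))
    if not sets:
        logger.warning("GMT file %s contains no gene sets", path)
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path,
              descriptions: dict[str, str] | None = None) -> Path:
    path = Path(path)
    descriptions = descriptions or {}
    with path.open("w") as fh:
        for gs in sets:
            desc = descriptions.get(gs.name, "na")
            fh.write("\t".join([gs.name, desc, *gs.symbols]) + "\n")
    return path


def read_survival_tsv(path: str | Path) -> list[SurvivalRecord]:
    """Read a survival table (columns sample_id, time, event)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = ["sample_id", "time", "event"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns {missing}")
    records = []
    for i, row in frame.iterrows():
        rowno = i + 2  # header is line 1
        try:
            time = float(row["time"])
            event = int(row["event"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path.name} row {rowno}: non-numeric time/event") from exc
        if event not in (0, 1):
            raise ValueError(f"{path.name} row {rowno}: event must be 0 or 1, got {row['event']}")
        if not time > 0:
            raise ValueError(f"{path.name} row {rowno}: time must be positive, got {row['time']}")
        records.append(SurvivalRecord(str(row["sample_id"]), time, event))
    return records


def write_survival_tsv(records: list[SurvivalRecord], path: str | Path) -> Path:
    path = Path(path)
    frame = pd.DataFrame(
        [(r.sample_id, r.time, r.event) for r in records],
        columns=["sample_id", "time", "event"])
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


SCORE_COLUMNS = ["sample_id", "es_true", "es_false", "score", "unstable", "sign_caution"]


def write_score_table(table: ScoreTable, path: str | Path) -> Path:
    path = Path(path)
    out = table.table.reset_index()
    out.columns = SCORE_COLUMNS
    out["unstable"] = out["unstable"].astype(int)
    out["sign_caution"] = out["sign_caution"].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def read_score_table(path: str | Path, method: str = "gsva_diff",
                     epsilon: float = 1e-10) -> ScoreTable:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in SCORE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"score table {Path(path).name}: missing columns {missing}")
    frame["unstable"] = frame["unstable"].astype(bool)
    frame["sign_caution"] = frame["sign_caution"].astype(bool)
    return ScoreTable(table=frame.set_index("sample_id"), method=method, epsilon=epsilon)
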