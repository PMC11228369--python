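"""Reading and writing the on-disk artifacts.

All expression data live in an :class:`ExpressionMatrix`: a genes x columns
pandas DataFrame plus a unit tag (``counts``, ``TPM`` or ``rank``) and a
dataset id.  Files may store either orientation; ``genes_in_rows=False``
transposes on load.  Duplicate gene ids are collapsed by summation (a
deterministic, conservative choice for count data) and the collapse is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

log = logging.getLogger(__name__)

VALID_UNITS = ("counts", "TPM", "rank")


@dataclass
class ExpressionMatrix:
    """Genes x cells (or genes x samples) expression values with metadata."""

    data: pd.DataFrame  # genes in rows, cells/samples in columns
    unit: str = "counts"
    dataset_id: str = ""

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene ids after load")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def column_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]


def _collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    if not df.index.has_duplicates:
        return df
    dupes = df.index[df.index.duplicated()].unique().tolist()
    log.warning("collapsing %d duplicated gene id(s) by sum: %s", len(dupes), dupes[:10])
    # groupby(sort=False) keeps first-occurrence order
    return df.groupby(level=0, sort=False).sum()


def read_expression_matrix(
    path: str | Path,
    format: str = "dense_tsv",
    unit: str = "counts",
    dataset_id: str | None = None,
    genes_in_rows: bool = True,
) -> ExpressionMatrix:
    """Load an expression matrix from a dense TSV/CSV or a CellRanger-style
    MTX directory (``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "dense_tsv":
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # pragma: no cover - message passthrough
            raise ValueError(f"malformed expression table {path}: {exc}") from exc
        if df.isna().to_numpy().any():
            bad = np.argwhere(df.isna().to_numpy())[0]
            raise ValueError(
                f"missing value in {path} at row {df.index[bad[0]]!r}, "
                f"column {df.columns[bad[1]]!r}"
            )
    elif format == "mtx_dir":
        df = _read_mtx_dir(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if not genes_in_rows:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df = _collapse_duplicate_genes(df)
    return ExpressionMatrix(df, unit=unit, dataset_id=dataset_id or path.stem)


def _find_one(path: Path, stems: tuple[str, ...]) -> Path:
    for stem in stems:
        for suffix in ("", ".tsv", ".txt", ".csv", ".mtx"):
            cand = path / f"{stem}{suffix}"
            if cand.exists():
                return cand
    raise FileNotFoundError(f"none of {stems} found under {path}")


def _read_mtx_dir(path: Path) -> pd.DataFrame:
    mtx = _find_one(path, ("matrix",))
    feats = _find_one(path, ("features", "genes"))
    bars = _find_one(path, ("barcodes",))
    try:
        m = scipy.io.mmread(mtx)
    except Exception as exc:
        raise ValueError(f"malformed MatrixMarket file {mtx}: {exc}") from exc
    genes = pd.read_csv(feats, sep="\t", header=None).iloc[:, 0].astype(str)
    cells = pd.read_csv(bars, sep="\t", header=None).iloc[:, 0].astype(str)
    if scipy.sparse.issparse(m):
        m = m.toarray()
    m = np.asarray(m)
    if m.shape != (len(genes), len(cells)):
        raise ValueError(
            f"dimension mismatch in {path}: matrix {m.shape}, "
            f"{len(genes)} features, {len(cells)} barcodes"
        )
    return pd.DataFrame(m, index=genes, columns=cells)


def write_expression_matrix(em: ExpressionMatrix, path: str | Path) -> None:
    em.data.to_csv(path, sep="\t", index_label="gene_id")


def write_table(records: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    """Write a result table as TSV with a header row."""
    if len(records) == 0:
        raise ValueError("refusing to write an empty table")
    records.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_signature_matrix(sig: pd.DataFrame, path: str | Path) -> None:
    """Signature matrix TSV: first column gene id, remaining columns exemplar ids."""
    write_table(sig, path, index=True)


def read_signature_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"signature matrix {path} has no exemplar columns")
    if df.isna().to_numpy().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"missing cell in signature matrix {path} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    df.index = df.index.astype(str)
    return df


SURVIVAL_COLUMNS = ("sample_id", "time", "event")


def read_survival_table(path: str | Path) -> pd.DataFrame:
    """Survival TSV: sample_id, time (>0), event (0/1), optional subtype, cohort."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SURVIVAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"survival table {path} lacks columns {missing}")
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not df["event"].isin((0, 1)).all():
        raise ValueError("event must be 0 (censored) or 1 (event)")
    return df
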