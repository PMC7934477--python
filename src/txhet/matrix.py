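"""Expression-matrix container shared by every analysis stage.

The matrix is genes x cells, holding non-negative normalized expression
values (quantile-normalized TPM-like units).  Per-cell metadata (subject,
condition, cell type, aligned read count, detected-gene fraction) rides
along in a DataFrame indexed by cell id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

#: metadata columns the QC and group-comparison stages look for
META_COLUMNS = (
    "subject",
    "condition",
    "cell_type",
    "aligned_read_count",
    "genes_detected_fraction",
)


class MatrixFormatError(ValueError):
    """Raised when an input file cannot be interpreted as an expression matrix."""


@dataclass
class ExpressionMatrix:
    """Genes x cells expression values with per-cell metadata.

    Parameters
    ----------
    values
        DataFrame with gene ids as the index and cell ids as columns.
        All entries must be finite and >= 0.
    cell_meta
        DataFrame indexed by cell id (same order as ``values.columns``).
        Missing metadata fields are simply absent columns.
    """

    values: pd.DataFrame
    cell_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=self.values.columns)
        if not self.values.index.is_unique:
            raise MatrixFormatError("gene ids are not unique")
        if not self.values.columns.is_unique:
            raise MatrixFormatError("cell ids are not unique")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise MatrixFormatError("expression values must be finite")
        if (arr < 0).any():
            raise MatrixFormatError("expression values must be non-negative")
        if not self.cell_meta.index.equals(self.values.columns):
            self.cell_meta = self.cell_meta.reindex(self.values.columns)

    # -- basic accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_array(self) -> np.ndarray:
        return self.values.to_numpy()

    # -- subsetting ------------------------------------------------------
    def subset_cells(self, cell_ids) -> "ExpressionMatrix":
        cols = list(cell_ids)
        return ExpressionMatrix(self.values[cols].copy(), self.cell_meta.loc[cols].copy())

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)].copy(), self.cell_meta.copy())

    def with_meta(self, meta: pd.DataFrame) -> "ExpressionMatrix":
        merged = self.cell_meta.join(meta, how="left")
        return ExpressionMatrix(self.values.copy(), merged)


def read_matrix(
    path: str | Path,
    format: str = "tsv",
    *,
    meta_path: str | Path | None = None,
    gene_path: str | Path | None = None,
    cell_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a genes x cells matrix from TSV/CSV (dense) or MTX (triplet).

    MTX input requires gene and cell name sidecars (one id per line); they
    default to ``<stem>.genes.txt`` / ``<stem>.cells.txt`` next to the file.
    An optional per-cell metadata table (TSV keyed by cell id) is merged in.
    """
    path = Path(path)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
    elif format == "mtx":
        gene_path = Path(gene_path) if gene_path else path.with_suffix("").with_suffix(".genes.txt")
        cell_path = Path(cell_path) if cell_path else path.with_suffix("").with_suffix(".cells.txt")
        if not gene_path.exists() or not cell_path.exists():
            raise MatrixFormatError("MTX input requires gene and cell name sidecar files")
        mat = scipy.io.mmread(path)
        genes = [ln.strip() for ln in Path(gene_path).read_text().splitlines() if ln.strip()]
        cells = [ln.strip() for ln in Path(cell_path).read_text().splitlines() if ln.strip()]
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        if dense.shape != (len(genes), len(cells)):
            raise MatrixFormatError(
                f"MTX shape {dense.shape} does not match sidecars ({len(genes)} genes, {len(cells)} cells)"
            )
        df = pd.DataFrame(dense, index=genes, columns=cells)
    else:
        raise MatrixFormatError(f"unknown format {format!r}")

    m = ExpressionMatrix(df)
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        meta.index = meta.index.astype(str)
        m = m.with_meta(meta)
    return m


def write_matrix(m: ExpressionMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write a matrix as dense TSV/CSV or as MTX triplet with name sidecars."""
    path = Path(path)
    if format in ("tsv", "csv"):
        m.values.to_csv(path, sep="\t" if format == "tsv" else ",")
    elif format == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(m.to_array()))
        path.with_suffix("").with_suffix(".genes.txt").write_text("\n".join(m.gene_ids) + "\n")
        path.with_suffix("").with_suffix(".cells.txt").write_text("\n".join(m.cell_ids) + "\n")
    else:
        raise MatrixFormatError(f"unknown format {format!r}")
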