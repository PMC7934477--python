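"""Quantile normalization and cell-level quality control.

QC removes cells in four fixed stages: too few aligned reads, too small a
fraction of detected genes, a low neural-to-embryonic (N-E) marker ratio,
and finally an outlier stage that drops cells whose average Spearman
correlation with the other cells of their condition falls more than
``mad_k`` median-absolute-deviations below the condition median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import ExpressionMatrix


@dataclass
class QCReport:
    """Per-stage cell attrition of :func:`qc_filter` (stages in applied order)."""

    n_input_cells: int
    n_removed_by_reads: int = 0
    n_removed_by_gene_fraction: int = 0
    n_removed_by_ne_index: int = 0
    n_removed_by_mad: int = 0
    kept_cell_ids: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_kept(self) -> int:
        return len(self.kept_cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": ["input", "reads", "gene_fraction", "ne_index", "mad", "kept"],
                "n": [
                    self.n_input_cells,
                    self.n_removed_by_reads,
                    self.n_removed_by_gene_fraction,
                    self.n_removed_by_ne_index,
                    self.n_removed_by_mad,
                    self.n_kept,
                ],
            }
        )


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every cell onto the common across-cell mean quantile profile.

    After normalization each cell's sorted value vector equals the across-cell
    mean of the per-rank sorted values.  Ties within a cell receive the mean
    of the reference values of the tied ranks, which keeps the transform
    idempotent.  Single-cell input is returned unchanged with a warning.
    """
    if m.n_cells < 2:
        warnings.warn("quantile normalization needs >= 2 cells; returning input unchanged")
        return m
    arr = m.to_array()
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr, dtype=float)
    n = arr.shape[0]
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(arr.shape[1]):
        ranks = rankdata(arr[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, reference)
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values, m.cell_meta.copy())


def ne_index(m: ExpressionMatrix, neural_genes, embryonic_genes) -> pd.Series:
    """Per-cell neural-to-embryonic marker ratio.

    Sum of neural-marker expression (NES, TUBB3 in the NPC setting) divided
    by the sum of embryonic-marker expression (POU5F1, NANOG).  A zero
    denominator with positive numerator gives ``+inf`` (clearly neural);
    0/0 gives ``NaN`` — an undefined marker state the filter keeps but flags.
    """
    missing = [g for g in list(neural_genes) + list(embryonic_genes) if g not in m.values.index]
    if missing:
        raise KeyError(f"marker genes absent from matrix: {missing}")
    num = m.values.loc[list(neural_genes)].sum(axis=0)
    den = m.values.loc[list(embryonic_genes)].sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num.to_numpy() / den.to_numpy()
    return pd.Series(ratio, index=m.values.columns, name="ne_index")


def average_spearman(arr: np.ndarray) -> np.ndarray:
    """Average Spearman correlation of each cell (column) with all other cells."""
    ranks = np.apply_along_axis(rankdata, 0, arr)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(ranks, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    n = corr.shape[0]
    return (corr.sum(axis=0) - np.diag(corr)) / (n - 1)


def qc_filter(
    m: ExpressionMatrix,
    min_reads: float = 2e5,
    min_gene_fraction: float = 0.15,
    ne_threshold: float = 2.0,
    mad_k: float = 5.0,
    neural_genes=("NES", "TUBB3"),
    embryonic_genes=("POU5F1", "NANOG"),
    mad_per_condition: bool = True,
    mad_two_sided: bool = False,
) -> tuple[ExpressionMatrix, QCReport]:
    """Apply the four QC stages in order: reads, gene fraction, N-E index, MAD.

    Stages whose inputs are unavailable (missing metadata columns, missing
    marker genes, or fewer than 3 surviving cells for the MAD stage) are
    skipped with a recorded warning rather than failing.
    """
    report = QCReport(n_input_cells=m.n_cells)
    keep = pd.Series(True, index=m.values.columns)

    if "aligned_read_count" in m.cell_meta.columns and m.cell_meta["aligned_read_count"].notna().any():
        fail = m.cell_meta["aligned_read_count"].astype(float) < min_reads
        report.n_removed_by_reads = int(fail[keep].sum())
        keep &= ~fail.fillna(False)
    else:
        report.warnings.append("aligned_read_count missing: read-count stage skipped")

    if "genes_detected_fraction" in m.cell_meta.columns and m.cell_meta["genes_detected_fraction"].notna().any():
        fail = m.cell_meta["genes_detected_fraction"].astype(float) < min_gene_fraction
        report.n_removed_by_gene_fraction = int(fail[keep].sum())
        keep &= ~fail.fillna(False)
    else:
        report.warnings.append("genes_detected_fraction missing: gene-fraction stage skipped")

    try:
        ratio = ne_index(m, neural_genes, embryonic_genes)
    except KeyError:
        report.warnings.append("marker genes missing: N-E stage skipped")
    else:
        fail = ratio < ne_threshold  # NaN compares False: undefined state kept
        report.n_removed_by_ne_index = int(fail[keep].sum())
        keep &= ~fail

    kept_ids = list(m.values.columns[keep])
    sub = m.subset_cells(kept_ids)
    if sub.n_cells < 3:
        report.warnings.append("fewer than 3 cells before MAD stage: skipped")
    else:
        conditions = (
            sub.cell_meta["condition"]
            if mad_per_condition and "condition" in sub.cell_meta.columns
            else pd.Series("all", index=sub.values.columns)
        )
        drop: list[str] = []
        for _, ids in sub.values.columns.to_series().groupby(conditions.fillna("all").to_numpy()):
            cols = list(ids)
            if len(cols) < 3:
                continue
            avg = average_spearman(sub.values[cols].to_numpy())
            med = np.median(avg)
            mad = np.median(np.abs(avg - med))
            dev = np.abs(avg - med) if mad_two_sided else med - avg
            drop.extend(np.asarray(cols)[dev > mad_k * mad])
        report.n_removed_by_mad = len(drop)
        kept_ids = [c for c in kept_ids if c not in set(drop)]

    report.kept_cell_ids = kept_ids
    return m.subset_cells(kept_ids), report
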