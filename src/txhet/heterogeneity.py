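"""Population-level heterogeneity statistics.

Two complementary, depth-robust measures:

* **detection median** — rank genes within each cell by expression, take the
  k genes with the largest across-cell average rank, and report the median
  fraction of cells in which those genes are detected (> 0).  Values near 1
  mean the population expresses its top program coherently; low values mean
  high cell-to-cell heterogeneity.  Being rank-based, the statistic is
  invariant to per-cell depth scaling.
* **intra-condition distance** — 1 − Pearson correlation between the
  expression profiles of every pair of cells from the same condition; its
  distribution widens and shifts upward as a population becomes more
  heterogeneous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix

#: sentinel returned for subjects with too few cells
EXCLUDED = "excluded"


def detection_median(m: ExpressionMatrix, k: int = 200, min_cells: int | None = None):
    """Median detection fraction over the k genes with the largest average
    within-cell expression rank.

    ``min_cells`` is enforced only when given (multi-subject mode); a matrix
    with fewer cells returns the sentinel ``"excluded"``.
    """
    if k > m.n_genes:
        raise ValueError(f"k={k} exceeds number of genes ({m.n_genes})")
    if min_cells is not None and m.n_cells < min_cells:
        return EXCLUDED
    arr = m.to_array()
    # ascending ranks within each cell, average on ties: largest rank = highest expression
    ranks = stats.rankdata(arr, axis=0, method="average")
    avg_rank = ranks.mean(axis=1)
    # stable top-k selection: break average-rank ties by gene order
    top = np.argsort(-avg_rank, kind="stable")[:k]
    detect_frac = (arr[top] > 0).mean(axis=1)
    return float(np.median(detect_frac))


def detection_medians_by_subject(
    m: ExpressionMatrix,
    k: int = 200,
    min_cells: int = 50,
    subject_col: str = "subject",
    celltype_col: str | None = "cell_type",
) -> pd.DataFrame:
    """Per-(subject, cell type) detection medians; small groups recorded as excluded."""
    meta = m.cell_meta
    if subject_col not in meta.columns:
        raise KeyError(f"metadata column {subject_col!r} missing")
    keys = [subject_col] + ([celltype_col] if celltype_col and celltype_col in meta.columns else [])
    rows = []
    for key, ids in meta.groupby(keys, observed=True).groups.items():
        key = key if isinstance(key, tuple) else (key,)
        sub = m.subset_cells(list(ids))
        stat = detection_median(sub, k=k, min_cells=min_cells) if k <= sub.n_genes else EXCLUDED
        rows.append(dict(zip(keys, key)) | {"n_cells": sub.n_cells, "detection_median": stat})
    return pd.DataFrame(rows)


def detection_group_test(values, groups, direction: str = "less"):
    """One-sided Wilcoxon rank-sum test on per-subject detection medians.

    ``direction="less"`` tests whether the first group (e.g. disease) has
    smaller medians than the second (healthy).  Exact p for small samples.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(levels)}")
    a = values[groups == levels[0]]
    b = values[groups == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 subjects")
    res = stats.mannwhitneyu(a, b, alternative=direction)
    return float(res.statistic), float(res.pvalue)


@dataclass
class DistanceDistribution:
    """Pairwise 1 − Pearson distances within each condition of a pair."""

    distances: dict[str, np.ndarray]
    gene_ids: list[str] = field(default_factory=list)
    means: dict[str, float] = field(default_factory=dict)
    mean_difference: float | None = None


def expression_gene_filter(
    matrices, min_detect_frac: float = 0.5, min_mean: float = 5.0
) -> list[str]:
    """Genes detected in >= ``min_detect_frac`` of cells with mean expression
    > ``min_mean`` in *every* supplied matrix (joint filter)."""
    keep = None
    for m in matrices:
        arr = m.to_array()
        ok = ((arr > 0).mean(axis=1) >= min_detect_frac) & (arr.mean(axis=1) > min_mean)
        keep = ok if keep is None else (keep & ok)
    genes = [g for g, f in zip(matrices[0].gene_ids, keep) if f]
    return genes


def _pairwise_distances(arr: np.ndarray) -> np.ndarray:
    corr = np.corrcoef(arr, rowvar=False)
    iu = np.triu_indices(corr.shape[0], k=1)
    return 1.0 - corr[iu]


def intra_condition_distance(
    matrices: dict[str, ExpressionMatrix],
    min_detect_frac: float | None = 0.5,
    min_mean: float | None = 5.0,
    all_genes: bool = False,
) -> DistanceDistribution:
    """Distribution of 1 − Pearson distances between all cell pairs, per condition.

    When more than one condition is supplied the expression filter is applied
    jointly (a gene must pass in every condition).  ``all_genes=True`` skips
    the filter (the whole-transcriptome variant used for droplet data).
    """
    mats = list(matrices.values())
    for m in mats:
        if m.n_cells < 3:
            raise ValueError("each condition needs >= 3 cells")
    if all_genes:
        genes = mats[0].gene_ids
    else:
        genes = expression_gene_filter(mats, min_detect_frac, min_mean)
        if not genes:
            raise ValueError(
                f"no genes pass the expression filter (detect frac >= {min_detect_frac}, mean > {min_mean})"
            )
    dists = {name: _pairwise_distances(m.subset_genes(genes).to_array()) for name, m in matrices.items()}
    means = {name: float(np.mean(d)) for name, d in dists.items()}
    diff = None
    if len(means) == 2:
        a, b = means.values()
        diff = b - a
    return DistanceDistribution(distances=dists, gene_ids=genes, means=means, mean_difference=diff)


def distance_group_test(d1: np.ndarray, d2: np.ndarray, unit: str = "cell_pair"):
    """Compare two intra-condition distance distributions.

    ``unit="cell_pair"``: two-sample t-test on the raw pairwise distances
    (isogenic-pair analysis).  ``unit="subject_median"``: Wilcoxon rank-sum
    on per-subject medians (cohort analysis) — pass the medians as d1/d2.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.size == 0 or d2.size == 0:
        raise ValueError("empty distance distribution")
    if unit == "cell_pair":
        if np.std(d1) == 0 and np.std(d2) == 0:
            warnings.warn("degenerate variance: falling back to rank-sum test")
            res = stats.mannwhitneyu(d1, d2, alternative="two-sided")
        else:
            res = stats.ttest_ind(d1, d2)
    elif unit == "subject_median":
        res = stats.mannwhitneyu(d1, d2, alternative="two-sided")
    else:
        raise ValueError(f"unknown unit {unit!r}")
    return float(res.statistic), float(res.pvalue)
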