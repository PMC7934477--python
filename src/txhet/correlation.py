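"""Gene-correlation structure and its loss between conditions.

A transcriptionally disorganized population shows weaker gene-gene
correlations across the regulatory network.  This module computes the
Spearman correlation matrix per condition, each gene's average squared
correlation with all other genes, the per-pair squared-correlation
difference (WT² − mutant², so positive = decorrelation in the mutant),
the dispersion of correlations with subsample replicates, and a k-means
extraction of the main cluster of genes that decorrelate together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .heterogeneity import expression_gene_filter
from .matrix import ExpressionMatrix


@dataclass
class CorrelationSummary:
    """Per-condition Spearman gene-gene correlation structure for a WT/mutant pair."""

    c_wt: pd.DataFrame
    c_mut: pd.DataFrame
    avg_sq: pd.DataFrame          # per gene x condition, diagonal excluded
    sq_diff: pd.DataFrame         # (C^WT)^2 - (C^mut)^2 per gene pair
    degenerate_genes: list[str] = field(default_factory=list)


def spearman_matrix(arr: np.ndarray) -> np.ndarray:
    """Gene x gene Spearman correlation (genes are rows, cells columns)."""
    ranks = stats.rankdata(arr, axis=1, method="average")
    with np.errstate(invalid="ignore"):
        return np.corrcoef(ranks)


def gene_correlations(
    m_wt: ExpressionMatrix,
    m_mut: ExpressionMatrix,
    min_detect_frac: float | None = 0.5,
    min_mean: float | None = 5.0,
    all_genes: bool = False,
) -> CorrelationSummary:
    """Spearman correlation matrices per condition plus derived summaries.

    Genes constant in either condition yield undefined correlations; they are
    flagged, their rows/columns set to NaN, and they are excluded from the
    average-squared-correlation of other genes.
    """
    if m_wt.n_cells < 10 or m_mut.n_cells < 10:
        raise ValueError("need >= 10 cells per condition")
    genes = m_wt.gene_ids if all_genes else expression_gene_filter([m_wt, m_mut], min_detect_frac, min_mean)
    if not genes:
        raise ValueError("no genes pass the expression filter")
    a_wt = m_wt.subset_genes(genes).to_array()
    a_mut = m_mut.subset_genes(genes).to_array()

    r_wt = stats.rankdata(a_wt, axis=1, method="average")
    r_mut = stats.rankdata(a_mut, axis=1, method="average")
    # a gene is degenerate when its rank vector is constant in either condition
    bad_mask = (r_wt.std(axis=1) == 0) | (r_mut.std(axis=1) == 0)
    degenerate = [g for g, bad in zip(genes, bad_mask) if bad]
    with np.errstate(invalid="ignore"):
        c_wt = np.corrcoef(r_wt)
        c_mut = np.corrcoef(r_mut)
    bad = np.isin(genes, degenerate)
    for c in (c_wt, c_mut):
        c[bad, :] = np.nan
        c[:, bad] = np.nan
        np.fill_diagonal(c, 1.0)

    n = len(genes)
    avg = {}
    for name, c in (("wt", c_wt), ("mut", c_mut)):
        sq = c**2
        np.fill_diagonal(sq, np.nan)  # exclude the diagonal from the average
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows of degenerate genes
            avg[name] = np.nanmean(sq, axis=1) if n > 1 else np.full(n, np.nan)
    sq_diff = c_wt**2 - c_mut**2
    np.fill_diagonal(sq_diff, 0.0)

    idx = pd.Index(genes, name="gene_id")
    return CorrelationSummary(
        c_wt=pd.DataFrame(c_wt, index=idx, columns=idx),
        c_mut=pd.DataFrame(c_mut, index=idx, columns=idx),
        avg_sq=pd.DataFrame(avg, index=idx),
        sq_diff=pd.DataFrame(sq_diff, index=idx, columns=idx),
        degenerate_genes=degenerate,
    )


def _offdiag_sd(c: np.ndarray) -> float:
    iu = np.triu_indices(c.shape[0], k=1)
    vals = c[iu]
    return float(np.nanstd(vals))


def correlation_sd_compare(
    m_wt: ExpressionMatrix,
    m_mut: ExpressionMatrix,
    genes: list[str],
    n_replicates: int = 10,
    subsample_frac: float = 0.8,
    seed: int = 0,
):
    """Dispersion of gene-gene correlations per condition with replicate error bars.

    Each replicate subsamples an equal number of cells from both conditions
    without replacement and recomputes the sd of the off-diagonal Spearman
    correlations.  Returns per-condition (mean sd, sd over replicates) and a
    two-tailed t-test across replicates.
    """
    if n_replicates < 2:
        raise ValueError("need >= 2 replicates")
    n_cells = int(round(subsample_frac * min(m_wt.n_cells, m_mut.n_cells)))
    if n_cells < 10:
        raise ValueError(f"subsample of {n_cells} cells is too small (< 10)")
    rng = np.random.default_rng(seed)
    sds: dict[str, list[float]] = {"wt": [], "mut": []}
    for _ in range(n_replicates):
        for name, m in (("wt", m_wt), ("mut", m_mut)):
            cols = rng.choice(m.n_cells, size=n_cells, replace=False)
            arr = m.subset_genes(genes).to_array()[:, cols]
            sds[name].append(_offdiag_sd(spearman_matrix(arr)))
    res = stats.ttest_ind(sds["wt"], sds["mut"])
    out = {name: (float(np.mean(v)), float(np.std(v, ddof=1))) for name, v in sds.items()}
    return out, float(res.statistic), float(res.pvalue)


@dataclass
class ClusterResult:
    """Largest k-means cluster of co-decorrelating genes."""

    members: set[str]
    inertia: float
    silhouette: float
    no_structure: bool


def declining_cluster(
    summary: CorrelationSummary,
    k: int = 2,
    n_restarts: int = 6,
    n_runs: int = 10,
    max_iter: int = 10_000,
    seed: int = 0,
    silhouette_floor: float = 0.1,
    select: str = "declining",
) -> ClusterResult:
    """k-means on the rows of the squared-correlation-difference matrix.

    The algorithm is run ``n_runs`` times (each with ``n_restarts`` internal
    restarts) and the run with the lowest within-cluster sum of squares wins.
    ``select="declining"`` (default) returns the cluster whose members show
    the strongest average loss of correlation (highest mean sq_diff row
    mean) — the cluster of interest even when it is the minority;
    ``select="largest"`` returns the biggest cluster regardless of signal.
    A silhouette below ``silhouette_floor`` flags the partition as
    "no structure".
    """
    genes = np.asarray(summary.sq_diff.index)
    ok = ~np.isin(genes, summary.degenerate_genes)
    X = summary.sq_diff.to_numpy()[np.ix_(ok, ok)]
    genes = genes[ok]
    keep = ~np.isnan(X).any(axis=1)
    X, genes = X[np.ix_(keep, keep)], genes[keep]
    if k > len(genes):
        raise ValueError(f"k={k} exceeds number of usable genes ({len(genes)})")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_runs):
        km = KMeans(n_clusters=k, n_init=n_restarts, max_iter=max_iter,
                    random_state=int(rng.integers(2**31 - 1)))
        labels = km.fit_predict(X)
        if best is None or km.inertia_ < best[0]:
            best = (km.inertia_, labels)
    inertia, labels = best
    if select == "largest":
        chosen = int(np.argmax(np.bincount(labels, minlength=k)))
    elif select == "declining":
        row_signal = np.nanmean(X, axis=1)  # genes losing correlation sit high
        scores = [row_signal[labels == c].mean() if (labels == c).any() else -np.inf for c in range(k)]
        if not np.isfinite(np.max(scores)):
            chosen = int(np.argmax(np.bincount(labels, minlength=k)))
        else:
            chosen = int(np.argmax(scores))
    else:
        raise ValueError(f"unknown select rule {select!r}")
    sil = float(silhouette_score(X, labels)) if len(set(labels)) > 1 else 0.0
    return ClusterResult(
        members=set(genes[labels == chosen]),
        inertia=float(inertia),
        silhouette=sil,
        no_structure=sil < silhouette_floor,
    )


def cluster_enrichment(cluster, annotation_sets: dict[str, set], background) -> pd.DataFrame:
    """Hypergeometric enrichment of a gene cluster against annotation sets.

    Exact upper-tail p on the overlap between the cluster and each annotation
    set, with the expressed-gene background as the universe; BH adjustment
    across the supplied sets.
    """
    background = set(background)
    cluster = set(cluster)
    if not cluster <= background:
        raise ValueError("cluster must be a subset of the background")
    rows = []
    for name, ann in annotation_sets.items():
        ann_bg = set(ann) & background
        overlap = len(cluster & ann_bg)
        if not ann_bg:
            warnings.warn(f"annotation set {name!r} is disjoint from the background")
            rows.append({"set": name, "overlap": 0, "set_size": 0, "p": 1.0})
            continue
        p = float(stats.hypergeom.sf(overlap - 1, len(background), len(ann_bg), len(cluster)))
        rows.append({"set": name, "overlap": overlap, "set_size": len(ann_bg), "p": min(p, 1.0)})
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    return df
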