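"""Differential-variability calling between two conditions.

The analysis isolates changes in expression *variability* from changes in
expression *level*:

1. genes are restricted to those expressed in at least half the cells with
   mean > 5 normalized counts in both conditions, and to similar means via
   the mean-difference index |(M_mut − M_wt)/(M_mut + M_wt)| < 0.05;
2. model-based DVSM calls use each gene's mixture classification — two pure
   Gaussians are compared by a bootstrap CI on their sd ratio (type I), a
   pure Gaussian against a low-Gaussian profile is called more variable in
   the mixed condition (type II);
3. CV-based DVSM calls bootstrap the ratio of *trimmed* CVs (top and bottom
   5% of cells removed) and add a label-permutation p-value;
4. for all genes, the trimmed CV is converted to a mean-decorrelated
   variability rank score by ranking within sliding windows of 150
   mean-sorted genes, and DV genes are those whose score difference between
   conditions exceeds 1 or 2 sd of the score-difference distribution.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .correlation import cluster_enrichment
from .heterogeneity import expression_gene_filter
from .matrix import ExpressionMatrix
from .mixture import LOW_GAUSSIAN, PURE_GAUSSIAN, MixtureFit

# DVSM call labels
MORE_VARIABLE_MUT_TYPE_I = "more_variable_mut_typeI"
MORE_VARIABLE_MUT_TYPE_II = "more_variable_mut_typeII"
MORE_VARIABLE_WT_TYPE_I = "more_variable_wt_typeI"
MORE_VARIABLE_WT_TYPE_II = "more_variable_wt_typeII"
NOT_DV = "not_dv"
NOT_APPLICABLE = "not_applicable"


def mean_difference_index(mean_wt: float, mean_mut: float) -> float:
    """(M_mut − M_wt)/(M_mut + M_wt); antisymmetric under condition swap."""
    if mean_wt == 0 and mean_mut == 0:
        return np.nan
    return (mean_mut - mean_wt) / (mean_mut + mean_wt)


def similar_mean_filter(
    m_wt: ExpressionMatrix,
    m_mut: ExpressionMatrix,
    cutoff: float = 0.05,
    min_detect_frac: float = 0.5,
    min_mean: float = 5.0,
) -> list[str]:
    """Genes passing the expression filter in both conditions with
    |mean-difference index| strictly below ``cutoff``."""
    genes = expression_gene_filter([m_wt, m_mut], min_detect_frac, min_mean)
    mw = m_wt.subset_genes(genes).to_array().mean(axis=1)
    mm = m_mut.subset_genes(genes).to_array().mean(axis=1)
    idx = (mm - mw) / (mm + mw)
    return [g for g, v in zip(genes, idx) if abs(v) < cutoff]


def trimmed_cv(x, trim: float = 0.05) -> float:
    """Coefficient of variation after removing floor(n*trim) values per tail.

    Robust to the 1-2 extreme cells that can double a raw CV estimate.
    Returns 0 for a constant trimmed sample and NaN when the trimmed mean is 0.
    """
    x = np.sort(np.asarray(x, dtype=float).ravel())
    n = x.size
    if n < 20:
        raise ValueError(f"need >= 20 observations, got {n}")
    cut = max(int(np.floor(n * trim)), 1)
    t = x[cut : n - cut]
    mean = t.mean()
    if mean == 0:
        return np.nan
    return float(t.std(ddof=1) / mean)


def _trimmed_cv_rows(arr: np.ndarray, trim: float = 0.05) -> np.ndarray:
    """Row-wise trimmed CV for a 2-D array (resampling helper)."""
    n = arr.shape[1]
    cut = max(int(np.floor(n * trim)), 1)
    s = np.sort(arr, axis=1)[:, cut : n - cut]
    mean = s.mean(axis=1)
    sd = s.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(mean != 0, sd / mean, np.nan)


def dvsm_model_call(
    x_wt,
    x_mut,
    fit_wt: MixtureFit,
    fit_mut: MixtureFit,
    n_boot: int = 10_000,
    ci: float = 0.95,
    seed: int = 0,
    pure_threshold: float = 0.9,
    mixed_threshold: float = 0.8,
):
    """Model-based DVSM call for one similar-mean gene.

    Returns ``(call, (ci_lo, ci_hi))``; the CI is on the mutant/WT sd ratio
    and is only computed in the two-pure-Gaussian (type I) case.
    """
    if not (fit_wt.converged and fit_mut.converged):
        return NOT_APPLICABLE, (np.nan, np.nan)
    wt_pure = fit_wt.shape_class == PURE_GAUSSIAN
    mut_pure = fit_mut.shape_class == PURE_GAUSSIAN
    if wt_pure and mut_pure:
        lo, hi = bootstrap_ratio_ci(np.asarray(x_wt, float), np.asarray(x_mut, float),
                                    statistic="sd", n_boot=n_boot, ci=ci, seed=seed)
        if lo > 1:
            return MORE_VARIABLE_MUT_TYPE_I, (lo, hi)
        if hi < 1:
            return MORE_VARIABLE_WT_TYPE_I, (lo, hi)
        return NOT_DV, (lo, hi)
    if wt_pure and fit_mut.pi[0] < mixed_threshold:
        return MORE_VARIABLE_MUT_TYPE_II, (np.nan, np.nan)
    if mut_pure and fit_wt.pi[0] < mixed_threshold:
        return MORE_VARIABLE_WT_TYPE_II, (np.nan, np.nan)
    return NOT_APPLICABLE, (np.nan, np.nan)


def bootstrap_ratio_ci(
    x_wt: np.ndarray,
    x_mut: np.ndarray,
    statistic: str = "sd",
    n_boot: int = 10_000,
    ci: float = 0.95,
    seed: int = 0,
    trim: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI on the mutant/WT ratio of a spread statistic.

    ``statistic`` is ``"sd"`` (type-I model comparison) or ``"trimmed_cv"``.
    Each of the ``n_boot`` replicate pairs resamples both conditions with
    replacement and records the ratio.
    """
    rng = np.random.default_rng(seed)
    boots = {}
    for key, x in (("wt", x_wt), ("mut", x_mut)):
        idx = rng.integers(0, x.size, size=(n_boot, x.size))
        draws = x[idx]
        if statistic == "sd":
            boots[key] = draws.std(axis=1, ddof=1)
        elif statistic == "trimmed_cv":
            boots[key] = _trimmed_cv_rows(draws, trim)
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = boots["mut"] / boots["wt"]
    ratio = ratio[np.isfinite(ratio)]
    alpha = (1 - ci) / 2
    lo, hi = np.quantile(ratio, [alpha, 1 - alpha])
    return float(lo), float(hi)


def dvsm_cv_call(
    x_wt,
    x_mut,
    n_boot: int = 10_000,
    n_perm: int = 10_000,
    ci: float = 0.95,
    seed: int = 0,
    trim: float = 0.05,
):
    """Trimmed-CV DVSM call: bootstrap CI on the CV ratio plus a permutation p.

    The permutation test pools the cells, reshuffles condition labels, and
    recomputes |log CV ratio|; p has resolution 1/(n_perm + 1), so the
    smallest reportable p is 1/(n_perm + 1).
    """
    x_wt = np.asarray(x_wt, dtype=float).ravel()
    x_mut = np.asarray(x_mut, dtype=float).ravel()
    cv_wt = trimmed_cv(x_wt, trim)
    cv_mut = trimmed_cv(x_mut, trim)
    if not np.isfinite(cv_wt) or not np.isfinite(cv_mut) or cv_wt == 0:
        return (np.nan, np.nan), NOT_APPLICABLE, np.nan

    lo, hi = bootstrap_ratio_ci(x_wt, x_mut, statistic="trimmed_cv",
                                n_boot=n_boot, ci=ci, seed=seed)
    if lo > 1:
        call = MORE_VARIABLE_MUT_TYPE_I
    elif hi < 1:
        call = MORE_VARIABLE_WT_TYPE_I
    else:
        call = NOT_DV

    rng = np.random.default_rng(seed + 1)
    pool = np.concatenate([x_wt, x_mut])
    obs = abs(np.log(cv_mut / cv_wt)) if cv_mut > 0 else np.inf
    perms = rng.permuted(np.broadcast_to(pool, (n_perm, pool.size)).copy(), axis=1)
    cv_a = _trimmed_cv_rows(perms[:, : x_wt.size], trim)
    cv_b = _trimmed_cv_rows(perms[:, x_wt.size :], trim)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.abs(np.log(cv_b / cv_a))
    stat = stat[np.isfinite(stat)]
    p = (1 + np.sum(stat >= obs)) / (stat.size + 1)
    return (lo, hi), call, float(p)


def variability_rank_score(means, cvs, window: int = 150) -> pd.Series:
    """Mean-decorrelated variability score from windowed CV ranks.

    Genes are sorted by mean expression; within every group of ``window``
    consecutive genes (stride 1) each gene's trimmed CV is ranked and the
    rank rescaled to [0, 1].  A gene's score is the average over all windows
    containing it; the ``window − 1`` genes at each extreme of the mean
    ordering belong to fewer windows and are dropped (NaN).
    """
    means = pd.Series(means, dtype=float)
    cvs = pd.Series(cvs, dtype=float).reindex(means.index)
    n = len(means)
    if window < 2:
        raise ValueError("window must be >= 2")
    if n < 2 * window - 1:
        # n = 2*window - 1 is the smallest panel where any gene belongs to all windows
        raise ValueError(f"need at least {2 * window - 1} genes, got {n}")
    order = np.argsort(means.to_numpy(), kind="stable")
    cv_sorted = cvs.to_numpy()[order]

    windows = np.lib.stride_tricks.sliding_window_view(cv_sorted, window)
    ranks = stats.rankdata(windows, axis=1, method="average")
    norm = (ranks - 1.0) / (window - 1.0)

    n_windows = windows.shape[0]
    sums = np.zeros(n)
    counts = np.zeros(n)
    w_idx = np.arange(n_windows)[:, None] + np.arange(window)[None, :]
    np.add.at(sums, w_idx.ravel(), norm.ravel())
    np.add.at(counts, w_idx.ravel(), 1.0)

    score_sorted = np.where(counts == window, sums / window, np.nan)
    scores = np.empty(n)
    scores[order] = score_sorted
    return pd.Series(scores, index=means.index, name="rank_score")


def dv_call(rank_wt: pd.Series, rank_mut: pd.Series, n_std: float = 2.0) -> pd.DataFrame:
    """Flag genes whose rank-score difference deviates from the mean difference
    by more than ``n_std`` standard deviations of the difference distribution."""
    common = rank_wt.dropna().index.intersection(rank_mut.dropna().index)
    if len(common) < 10:
        raise ValueError(f"need >= 10 genes with scores in both conditions, got {len(common)}")
    diff = rank_mut[common] - rank_wt[common]
    sd = float(diff.std(ddof=1))
    center = float(diff.mean())
    out = pd.DataFrame({"rank_diff": diff})
    if sd == 0:
        out["dv_call"] = "none"
        return out
    dev = diff - center
    out["dv_call"] = np.where(
        np.abs(dev) > n_std * sd,
        np.where(dev > 0, "more_variable_mut", "more_variable_wt"),
        "none",
    )
    return out


def differential_expression(
    m_wt: ExpressionMatrix,
    m_mut: ExpressionMatrix,
    min_log_sum: float = 3.0,
    min_log_fc: float = 1.0,
    alpha: float = 0.05,
    test: str = "ranksum",
) -> pd.DataFrame:
    """Differential expression with the expression-sum / fold-change / FDR rule.

    A gene is DE when mean(log2(x+1))_wt + mean(log2(x+1))_mut > ``min_log_sum``,
    the log2 means differ by at least ``min_log_fc`` (2-fold), and the
    BH-adjusted two-sample p-value is below ``alpha``.
    """
    if m_wt.n_cells < 3 or m_mut.n_cells < 3:
        raise ValueError("need >= 3 cells per condition")
    lw = np.log2(m_wt.to_array() + 1)
    lm = np.log2(m_mut.to_array() + 1)
    a_wt, a_mut = lw.mean(axis=1), lm.mean(axis=1)
    if test == "ranksum":
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.mannwhitneyu(lw, lm, axis=1, alternative="two-sided")
        p = np.nan_to_num(res.pvalue, nan=1.0)
    elif test == "ttest":
        res = stats.ttest_ind(lw, lm, axis=1)
        p = np.nan_to_num(res.pvalue, nan=1.0)
    else:
        raise ValueError(f"unknown test {test!r}")
    p_adj = multipletests(p, method="fdr_bh")[1]
    de = (a_wt + a_mut > min_log_sum) & (np.abs(a_mut - a_wt) >= min_log_fc) & (p_adj < alpha)
    return pd.DataFrame(
        {
            "a_wt": a_wt,
            "a_mut": a_mut,
            "log2_fc": a_mut - a_wt,
            "p": p,
            "p_adj": p_adj,
            "de": de,
        },
        index=pd.Index(m_wt.gene_ids, name="gene_id"),
    )


def dv_enrichment(dv_set, annotation, background) -> tuple[int, float]:
    """Upper-tail hypergeometric enrichment of a DV gene set (overlap, p)."""
    dv_set = set(dv_set)
    if not dv_set:
        warnings.warn("empty DV set: enrichment p = 1")
        return 0, 1.0
    df = cluster_enrichment(dv_set, {"annotation": set(annotation)}, background)
    return int(df["overlap"].iloc[0]), float(df["p"].iloc[0])


def variability_table(
    m_wt: ExpressionMatrix,
    m_mut: ExpressionMatrix,
    fits_wt: pd.DataFrame | None = None,
    fits_mut: pd.DataFrame | None = None,
    mean_cutoff: float = 0.05,
    n_boot: int = 10_000,
    n_perm: int = 10_000,
    window: int = 150,
    trim: float = 0.05,
    seed: int = 0,
    run_model_calls: bool = True,
) -> pd.DataFrame:
    """Per-gene variability summary table (means, index, trimmed CVs, rank
    scores, DVSM and DV calls) across the shared gene set.

    Model-based calls need per-gene mixture fit tables (from
    :func:`txhet.mixture.fit_matrix`); CV-based calls and rank scores are
    always computed.  Resampling substreams are derived from ``seed`` and the
    gene index, so results do not depend on iteration order.
    """
    genes = [g for g in m_wt.gene_ids if g in set(m_mut.gene_ids)]
    aw = m_wt.subset_genes(genes).to_array()
    am = m_mut.subset_genes(genes).to_array()
    mean_wt, mean_mut = aw.mean(axis=1), am.mean(axis=1)
    with np.errstate(invalid="ignore"):
        mdiff = (mean_mut - mean_wt) / (mean_mut + mean_wt)

    cv_wt = _trimmed_cv_rows(aw, trim) if aw.shape[1] >= 20 else np.full(len(genes), np.nan)
    cv_mut = _trimmed_cv_rows(am, trim) if am.shape[1] >= 20 else np.full(len(genes), np.nan)

    tab = pd.DataFrame(
        {
            "mean_wt": mean_wt,
            "mean_mut": mean_mut,
            "mean_diff_index": mdiff,
            "trimmed_cv_wt": cv_wt,
            "trimmed_cv_mut": cv_mut,
        },
        index=pd.Index(genes, name="gene_id"),
    )

    # rank scores on the full shared gene set, per condition means
    if len(genes) >= 2 * window:
        tab["rank_score_wt"] = variability_rank_score(tab["mean_wt"], tab["trimmed_cv_wt"], window)
        tab["rank_score_mut"] = variability_rank_score(tab["mean_mut"], tab["trimmed_cv_mut"], window)
        calls = dv_call(tab["rank_score_wt"], tab["rank_score_mut"], n_std=2.0)
        calls1 = dv_call(tab["rank_score_wt"], tab["rank_score_mut"], n_std=1.0)
        tab["rank_diff"] = calls["rank_diff"]
        tab["dv_call_2std"] = calls["dv_call"]
        tab["dv_call_1std"] = calls1["dv_call"]
        tab[["dv_call_2std", "dv_call_1std"]] = tab[["dv_call_2std", "dv_call_1std"]].fillna("none")
    else:
        tab["rank_score_wt"] = np.nan
        tab["rank_score_mut"] = np.nan
        tab["rank_diff"] = np.nan
        tab["dv_call_2std"] = "not_applicable"
        tab["dv_call_1std"] = "not_applicable"

    similar = set(similar_mean_filter(m_wt.subset_genes(genes), m_mut.subset_genes(genes), cutoff=mean_cutoff))
    tab["similar_mean"] = [g in similar for g in genes]

    tab["dvsm_model_call"] = NOT_APPLICABLE
    tab["dvsm_cv_call"] = NOT_APPLICABLE
    tab["cv_ratio_lo"] = np.nan
    tab["cv_ratio_hi"] = np.nan
    tab["perm_p"] = np.nan

    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in similar:
        i = gene_pos[g]
        sub_seed = (seed * 100_003 + i) % (2**31 - 1)
        if run_model_calls and fits_wt is not None and fits_mut is not None and g in fits_wt.index and g in fits_mut.index:
            fw, fm = fits_wt.loc[g], fits_mut.loc[g]
            fit_w = MixtureFit(pi=np.array([fw.pi_g, fw.pi_e, fw.pi_u]), mu=fw.mu, sigma=fw.sigma,
                               rate=fw.rate, loglik=fw.loglik, n_iter=int(fw.n_iter),
                               converged=bool(fw.converged), shape_class=fw.shape_class)
            fit_m = MixtureFit(pi=np.array([fm.pi_g, fm.pi_e, fm.pi_u]), mu=fm.mu, sigma=fm.sigma,
                               rate=fm.rate, loglik=fm.loglik, n_iter=int(fm.n_iter),
                               converged=bool(fm.converged), shape_class=fm.shape_class)
            call, _ = dvsm_model_call(aw[i], am[i], fit_w, fit_m, n_boot=n_boot, seed=sub_seed)
            tab.loc[g, "dvsm_model_call"] = call
        if aw.shape[1] >= 20 and am.shape[1] >= 20:
            (lo, hi), call, p = dvsm_cv_call(aw[i], am[i], n_boot=n_boot, n_perm=n_perm, seed=sub_seed, trim=trim)
            tab.loc[g, ["cv_ratio_lo", "cv_ratio_hi", "perm_p"]] = [lo, hi, p]
            tab.loc[g, "dvsm_cv_call"] = call

    sim_mask = tab["similar_mean"] & tab["perm_p"].notna()
    if sim_mask.any():
        tab.loc[sim_mask, "perm_p_adj"] = multipletests(tab.loc[sim_mask, "perm_p"], method="fdr_bh")[1]
    else:
        tab["perm_p_adj"] = np.nan
    return tab
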