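"""End-to-end orchestration: QC -> normalize -> heterogeneity -> correlation
structure -> mixture fits -> DVSM/DV -> enrichment.

Every stage parameter lives in :class:`PipelineConfig` with the analysis'
default value; a config file (YAML) round-trips losslessly, and the run
manifest records the seed and the full parameter snapshot so a run can be
reproduced exactly.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, asdict, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correlation import declining_cluster, gene_correlations, cluster_enrichment
from .heterogeneity import detection_median, distance_group_test, intra_condition_distance
from .io_qc import qc_filter, quantile_normalize
from .matrix import ExpressionMatrix, read_matrix
from .mixture import fit_matrix
from .variability import variability_table, differential_expression


class ConfigError(ValueError):
    """Invalid pipeline configuration; ``errors`` lists every problem found."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class PipelineConfig:
    # inputs
    wt_path: str | None = None
    mut_path: str | None = None
    matrix_path: str | None = None          # single matrix split by condition_col
    format: str = "tsv"
    wt_meta: str | None = None
    mut_meta: str | None = None
    meta_path: str | None = None
    condition_col: str = "condition"
    subject_col: str = "subject"
    celltype_col: str = "cell_type"
    gene_sets_path: str | None = None
    # QC
    run_qc: bool = True
    min_reads: float = 2e5
    min_gene_fraction: float = 0.15
    ne_threshold: float = 2.0
    mad_k: float = 5.0
    neural_genes: list = field(default_factory=lambda: ["NES", "TUBB3"])
    embryonic_genes: list = field(default_factory=lambda: ["POU5F1", "NANOG"])
    # normalization
    normalize: bool = True
    # heterogeneity
    k: int = 200
    min_cells: int = 50
    min_detect_frac: float = 0.5
    min_mean: float = 5.0
    # mixture EM
    em_starts: int = 5
    em_tol: float = 1e-8
    em_max_iter: int = 1000
    # differential variability
    mean_cutoff: float = 0.05
    n_boot: int = 10_000
    n_perm: int = 10_000
    window: int = 150
    n_std: float = 2.0
    trim: float = 0.05
    # clustering
    cluster_k: int = 2
    cluster_restarts: int = 6
    cluster_runs: int = 10
    cluster_max_iter: int = 10_000
    # run control
    seed: int = 0
    outdir: str = "txhet_out"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML config; all problems are reported at once.

    An empty file yields the full-default configuration.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    errors: list[str] = []
    known = {f.name: f for f in fields(PipelineConfig)}
    for key in raw:
        if key not in known:
            errors.append(f"unknown config key: {key!r}")
    cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known})
    errors.extend(check_config(cfg))
    if errors:
        raise ConfigError(errors)
    return cfg


def check_config(cfg: PipelineConfig) -> list[str]:
    errors = []
    if cfg.window < 2:
        errors.append("window must be >= 2")
    if not 0 <= cfg.trim < 0.5:
        errors.append("trim must be in [0, 0.5) (0.5 would empty the sample)")
    if cfg.k < 1:
        errors.append("k must be >= 1")
    if cfg.n_boot < 1 or cfg.n_perm < 1:
        errors.append("n_boot and n_perm must be >= 1")
    if cfg.mean_cutoff <= 0:
        errors.append("mean_cutoff must be > 0")
    if cfg.n_std not in (1, 2, 1.0, 2.0):
        errors.append("n_std must be 1 or 2")
    if cfg.em_starts < 1:
        errors.append("em_starts must be >= 1")
    return errors


def read_gmt(path: str | Path) -> dict[str, set]:
    """Read gene sets from a GMT file (name, description, genes per line)."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) >= 3:
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def _load_pair(cfg: PipelineConfig) -> tuple[ExpressionMatrix, ExpressionMatrix, tuple[str, str]]:
    if cfg.matrix_path:
        m = read_matrix(cfg.matrix_path, cfg.format, meta_path=cfg.meta_path)
        if cfg.condition_col not in m.cell_meta.columns:
            raise PipelineError(f"stage load: metadata column {cfg.condition_col!r} missing")
        levels = list(pd.unique(m.cell_meta[cfg.condition_col].dropna()))
        if len(levels) != 2:
            raise PipelineError(
                f"stage load: column {cfg.condition_col!r} has {len(levels)} levels, need exactly 2"
            )
        ids = m.cell_meta.groupby(cfg.condition_col, observed=True).groups
        return m.subset_cells(list(ids[levels[0]])), m.subset_cells(list(ids[levels[1]])), tuple(levels)
    if not (cfg.wt_path and cfg.mut_path):
        raise PipelineError("stage load: need wt_path+mut_path or matrix_path")
    m_wt = read_matrix(cfg.wt_path, cfg.format, meta_path=cfg.wt_meta)
    m_mut = read_matrix(cfg.mut_path, cfg.format, meta_path=cfg.mut_meta)
    return m_wt, m_mut, ("WT", "mutant")


def run_pipeline(
    config: PipelineConfig,
    m_wt: ExpressionMatrix | None = None,
    m_mut: ExpressionMatrix | None = None,
) -> dict:
    """Run the full two-condition analysis and write the report bundle.

    Matrices may be passed directly (e.g. fresh from the simulator); otherwise
    they are read from the configured paths.  Outputs: qc_report.tsv,
    heterogeneity.tsv, correlation_summary.tsv, cluster_genes.txt,
    mixture_fits_{wt,mut}.tsv, variability_table.tsv, de_table.tsv,
    enrichment.tsv (when gene sets are given) and manifest.json.
    Identical config + seed gives identical outputs.
    """
    errs = check_config(config)
    if errs:
        raise ConfigError(errs)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    log: dict = {"stages": {}}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except (ConfigError, PipelineError):
                failed_marker.write_text(name)
                raise
            except Exception as e:
                failed_marker.write_text(name)
                raise PipelineError(f"stage {name} failed: {e}") from e
        return wrap

    if m_wt is None or m_mut is None:
        m_wt, m_mut, names = stage("load")(lambda: _load_pair(config))
    else:
        names = ("WT", "mutant")
    log["stages"]["load"] = {"wt_cells": m_wt.n_cells, "mut_cells": m_mut.n_cells, "genes": m_wt.n_genes}

    # -- QC --------------------------------------------------------------
    if config.run_qc:
        def do_qc():
            frames = []
            out = []
            for label, m in (("wt", m_wt), ("mut", m_mut)):
                filt, rep = qc_filter(
                    m, min_reads=config.min_reads, min_gene_fraction=config.min_gene_fraction,
                    ne_threshold=config.ne_threshold, mad_k=config.mad_k,
                    neural_genes=config.neural_genes, embryonic_genes=config.embryonic_genes,
                )
                f = rep.to_frame()
                f.insert(0, "condition", label)
                frames.append(f)
                out.append(filt)
            pd.concat(frames).to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
            return out
        m_wt, m_mut = stage("qc")(do_qc)
        log["stages"]["qc"] = {"wt_cells": m_wt.n_cells, "mut_cells": m_mut.n_cells}

    # -- normalization ---------------------------------------------------
    if config.normalize:
        m_wt, m_mut = stage("normalize")(lambda: (quantile_normalize(m_wt), quantile_normalize(m_mut)))
        log["stages"]["normalize"] = {"applied": True}

    # -- heterogeneity ---------------------------------------------------
    def do_het():
        dist = intra_condition_distance(
            {names[0]: m_wt, names[1]: m_mut},
            min_detect_frac=config.min_detect_frac, min_mean=config.min_mean,
        )
        t, p = distance_group_test(dist.distances[names[0]], dist.distances[names[1]], unit="cell_pair")
        det = {name: detection_median(m, k=min(config.k, m.n_genes)) for name, m in
               ((names[0], m_wt), (names[1], m_mut))}
        rows = [
            {"metric": "mean_intra_distance", "condition": n_, "value": dist.means[n_]} for n_ in names
        ] + [
            {"metric": "detection_median", "condition": n_, "value": det[n_]} for n_ in names
        ] + [
            {"metric": "distance_mean_difference", "condition": "mut-wt", "value": dist.mean_difference},
            {"metric": "distance_test_t", "condition": "", "value": t},
            {"metric": "distance_test_p", "condition": "", "value": p},
        ]
        pd.DataFrame(rows).to_csv(outdir / "heterogeneity.tsv", sep="\t", index=False)
        return dist
    dist = stage("heterogeneity")(do_het)
    log["stages"]["heterogeneity"] = {"n_filter_genes": len(dist.gene_ids)}

    # -- correlation structure -------------------------------------------
    def do_corr():
        summary = gene_correlations(m_wt, m_mut, min_detect_frac=config.min_detect_frac,
                                    min_mean=config.min_mean)
        summary.avg_sq.to_csv(outdir / "correlation_summary.tsv", sep="\t")
        cluster = declining_cluster(summary, k=config.cluster_k, n_restarts=config.cluster_restarts,
                                    n_runs=config.cluster_runs, max_iter=config.cluster_max_iter,
                                    seed=config.seed)
        (outdir / "cluster_genes.txt").write_text("\n".join(sorted(cluster.members)) + "\n")
        return summary, cluster
    summary, cluster = stage("correlation")(do_corr)
    log["stages"]["correlation"] = {
        "n_genes": summary.sq_diff.shape[0],
        "cluster_size": len(cluster.members),
        "no_structure": cluster.no_structure,
    }

    # -- mixture fits (on the correlation/DVSM gene set) ------------------
    def do_fits():
        genes = list(summary.sq_diff.index)
        fw = fit_matrix(m_wt.subset_genes(genes), n_starts=config.em_starts, tol=config.em_tol,
                        max_iter=config.em_max_iter, seed=config.seed)
        fm = fit_matrix(m_mut.subset_genes(genes), n_starts=config.em_starts, tol=config.em_tol,
                        max_iter=config.em_max_iter, seed=config.seed + 1)
        fw.to_csv(outdir / "mixture_fits_wt.tsv", sep="\t")
        fm.to_csv(outdir / "mixture_fits_mut.tsv", sep="\t")
        return fw, fm
    fits_wt, fits_mut = stage("mixture")(do_fits)
    log["stages"]["mixture"] = {"n_fit": len(fits_wt)}

    # -- differential variability ----------------------------------------
    def do_var():
        tab = variability_table(
            m_wt, m_mut, fits_wt, fits_mut,
            mean_cutoff=config.mean_cutoff, n_boot=config.n_boot, n_perm=config.n_perm,
            window=config.window, trim=config.trim, seed=config.seed,
        )
        tab.to_csv(outdir / "variability_table.tsv", sep="\t")
        return tab
    var_tab = stage("variability")(do_var)
    dv_col = "dv_call_2std" if config.n_std == 2 else "dv_call_1std"
    n_dv = int((var_tab[dv_col] != "none").sum()) if dv_col in var_tab else 0
    log["stages"]["variability"] = {
        "n_genes": len(var_tab),
        "n_similar_mean": int(var_tab["similar_mean"].sum()),
        "n_dv": n_dv,
    }

    # -- differential expression -----------------------------------------
    def do_de():
        shared = [g for g in m_wt.gene_ids if g in set(m_mut.gene_ids)]
        de = differential_expression(m_wt.subset_genes(shared), m_mut.subset_genes(shared))
        de.to_csv(outdir / "de_table.tsv", sep="\t")
        return de
    de_tab = stage("differential_expression")(do_de)
    log["stages"]["differential_expression"] = {"n_de": int(de_tab["de"].sum())}

    # -- enrichment -------------------------------------------------------
    if config.gene_sets_path:
        def do_enrich():
            sets = read_gmt(config.gene_sets_path)
            background = set(var_tab.index)
            dv_set = set(var_tab.index[var_tab[dv_col] != "none"]) & background
            cluster_set = cluster.members & background
            frames = []
            for label, gs in (("dv", dv_set), ("cluster", cluster_set)):
                if sets:
                    df = cluster_enrichment(gs, sets, background)
                    df.insert(0, "query", label)
                    frames.append(df)
            enr = pd.concat(frames) if frames else pd.DataFrame()
            enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            return enr
        stage("enrichment")(do_enrich)

    manifest = {
        "txhet_version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "parameters": asdict(config),
        "log": log,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return {"manifest": manifest, "variability": var_tab, "de": de_tab,
            "correlation": summary, "cluster": cluster, "distance": dist}
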