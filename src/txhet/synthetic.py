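"""Synthetic expression data with planted ground truth.

The generator emulates quantile-normalized TPM-like single-cell data from a
two-condition isogenic design: per-gene distributions drawn from Gaussian,
exponential and near-zero-uniform families and their mixtures; genes with
equal means but unequal variances (the differential-variability signal); a
co-expression module driven by a shared latent factor whose loading can
differ between conditions (network decorrelation); and, for multi-subject
cohorts, per-cell sequencing-depth scaling and per-group zero inflation
(droplet-style dropout).  Every planted effect is reported in a
:class:`SyntheticTruth` so downstream stages can be tested for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .matrix import ExpressionMatrix, write_matrix

FAMILIES = ("gaussian", "exponential", "zero_spike", "mixture")
EFFECTS = ("none", "variance_shift", "gaussian_fraction_shift", "mean_shift")


@dataclass
class GeneSpec:
    """Distributional recipe for one gene.

    ``weights`` are the mixture proportions (pi_G, pi_E, pi_U); pure families
    put all weight on one component.  ``condition_effect`` describes how the
    second condition ("mutant") differs: ``variance_shift`` multiplies sigma
    by ``effect_magnitude`` keeping the mean identical by construction,
    ``gaussian_fraction_shift`` moves Gaussian weight into the other
    components, ``mean_shift`` multiplies the expression scale.
    """

    gene_id: str
    family: str = "gaussian"
    weights: tuple = (1.0, 0.0, 0.0)
    mu: float = 10.0
    sigma: float = 2.0
    rate: float = 0.2
    condition_effect: str = "none"
    effect_magnitude: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.condition_effect not in EFFECTS:
            raise ValueError(f"unknown condition effect {self.condition_effect!r}")
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (3,) or (w < 0).any() or abs(w.sum() - 1) > 1e-9:
            raise ValueError(f"weights must be a non-negative 3-vector summing to 1, got {self.weights}")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")

    def params_for(self, condition: int):
        """(weights, mu, sigma, rate) for condition 0 (WT) or 1 (mutant)."""
        w = np.asarray(self.weights, dtype=float)
        mu, sigma, rate = self.mu, self.sigma, self.rate
        if condition == 1:
            if self.condition_effect == "variance_shift":
                sigma = sigma * self.effect_magnitude
            elif self.condition_effect == "mean_shift":
                mu = mu * self.effect_magnitude
                rate = rate / self.effect_magnitude
            elif self.condition_effect == "gaussian_fraction_shift":
                drop = min(self.effect_magnitude, w[0])
                w = w + np.array([-drop, drop / 2, drop / 2])
        return w, mu, sigma, rate


@dataclass
class CohortConfig:
    """Size and nuisance-structure parameters of a simulated experiment.

    Defaults describe a disease-vs-control contrast: matched cell numbers,
    a ~16-fold spread of per-cell depth factors, and extra dropout in the
    second (disease) group, which is what drives the detection-median
    heterogeneity signal.
    """

    n_genes: int = 2000
    n_cells_per_condition: int = 200
    n_subjects_per_group: int = 10
    depth_range: tuple = (0.25, 4.0)
    zero_inflation_by_group: tuple = (0.0, 0.4)
    module_size: int = 50
    module_corr_by_condition: tuple = (0.8, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_cells_per_condition", "n_subjects_per_group"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.module_size < 0 or self.module_size > self.n_genes:
            raise ValueError("module_size must be in [0, n_genes]")
        lo, hi = self.depth_range
        if not (0 < lo <= hi):
            raise ValueError("depth_range must be 0 < lo <= hi")
        for z in self.zero_inflation_by_group:
            if not 0 <= z <= 1:
                raise ValueError("dropout probabilities must be in [0, 1]")
        for l in self.module_corr_by_condition:
            if not 0 <= abs(l) <= 1:
                raise ValueError("module loadings must be in [-1, 1]")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for key in ("depth_range", "zero_inflation_by_group", "module_corr_by_condition"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("depth_range", "zero_inflation_by_group", "module_corr_by_condition"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Planted ground truth of a simulated pair."""

    dv_gene_ids: set = field(default_factory=set)
    dv_direction: dict = field(default_factory=dict)   # gene -> "more_variable_mutant"/"more_variable_wt"
    de_gene_ids: set = field(default_factory=set)
    module_gene_ids: set = field(default_factory=set)
    marker_gene_ids: dict = field(default_factory=dict)  # role -> gene id

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in sorted(self.dv_gene_ids):
            rows.append({"gene_id": g, "label": "dv", "detail": self.dv_direction.get(g, "")})
        for g in sorted(self.de_gene_ids):
            rows.append({"gene_id": g, "label": "de", "detail": ""})
        for g in sorted(self.module_gene_ids):
            rows.append({"gene_id": g, "label": "module", "detail": ""})
        for role, g in sorted(self.marker_gene_ids.items()):
            rows.append({"gene_id": g, "label": "marker", "detail": role})
        return pd.DataFrame(rows, columns=["gene_id", "label", "detail"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# marker roles: neural markers high in every NPC-like cell, embryonic near zero
MARKER_ROLES = {
    "neural_1": "NES_like",
    "neural_2": "TUBB3_like",
    "embryonic_1": "POU5F1_like",
    "embryonic_2": "NANOG_like",
}


def default_gene_specs(
    config: CohortConfig,
    n_dv_variance: int | None = None,
    n_dv_fraction: int | None = None,
    n_de: int | None = None,
    dv_magnitude: float = 2.0,
    de_fold: float = 4.0,
    rng: np.random.Generator | None = None,
) -> tuple[list[GeneSpec], SyntheticTruth]:
    """A realistic gene panel: markers, a co-expression module, planted
    variance-shift / Gaussian-fraction-shift DV genes, planted fold-change DE
    genes, and a background of Gaussian (55%), exponential (25%), zero-spike
    (10%) and mixture (10%) genes with TPM-like scales.

    Planted counts default to 2.5% / 1% / 1.5% of the panel (50/20/30 genes
    on the default 2,000-gene panel).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_genes
    if n_dv_variance is None:
        n_dv_variance = max(1, round(n * 0.025))
    if n_dv_fraction is None:
        n_dv_fraction = max(1, round(n * 0.010))
    if n_de is None:
        n_de = max(1, round(n * 0.015))
    reserved = 4 + config.module_size + n_dv_variance + n_dv_fraction + n_de
    if reserved > n:
        raise ValueError(f"n_genes={n} too small for the requested planted structure ({reserved})")

    specs: list[GeneSpec] = []
    truth = SyntheticTruth()

    for role, gid in MARKER_ROLES.items():
        if role.startswith("neural"):
            specs.append(GeneSpec(gid, "gaussian", (1, 0, 0), mu=50.0, sigma=6.0))
        else:
            specs.append(GeneSpec(gid, "zero_spike", (0, 0, 1), mu=1.0, sigma=1.0, rate=1.0))
        truth.marker_gene_ids[role] = gid

    def scale_params():
        mu = float(np.exp(rng.normal(np.log(20.0), 0.6)))
        cv = float(rng.uniform(0.15, 0.45))
        return mu, max(cv * mu, 1e-3)

    for i in range(config.module_size):
        mu, _ = scale_params()
        specs.append(GeneSpec(f"MOD{i:04d}", "gaussian", (1, 0, 0), mu=max(mu, 15.0), sigma=0.12 * max(mu, 15.0)))
        truth.module_gene_ids.add(f"MOD{i:04d}")

    for i in range(n_dv_variance):
        mu = float(rng.uniform(10, 30))
        cv = float(rng.uniform(0.10, 0.15))  # low CV keeps truncation at 0 negligible
        gid = f"DVV{i:04d}"
        specs.append(GeneSpec(gid, "gaussian", (1, 0, 0), mu=mu, sigma=cv * mu,
                              condition_effect="variance_shift", effect_magnitude=dv_magnitude))
        truth.dv_gene_ids.add(gid)
        truth.dv_direction[gid] = "more_variable_mutant" if dv_magnitude > 1 else "more_variable_wt"

    for i in range(n_dv_fraction):
        mu = float(rng.uniform(10, 30))
        gid = f"DVF{i:04d}"
        specs.append(GeneSpec(gid, "gaussian", (1, 0, 0), mu=mu, sigma=0.15 * mu,
                              condition_effect="gaussian_fraction_shift", effect_magnitude=0.4))
        truth.dv_gene_ids.add(gid)
        truth.dv_direction[gid] = "more_variable_mutant"

    for i in range(n_de):
        mu, sigma = scale_params()
        gid = f"DE{i:04d}"
        specs.append(GeneSpec(gid, "gaussian", (1, 0, 0), mu=mu, sigma=sigma,
                              condition_effect="mean_shift", effect_magnitude=de_fold))
        truth.de_gene_ids.add(gid)

    families = rng.choice(["gaussian", "exponential", "zero_spike", "mixture"],
                          size=n - len(specs), p=[0.55, 0.25, 0.10, 0.10])
    for i, fam in enumerate(families):
        mu, sigma = scale_params()
        rate = 1.0 / float(np.exp(rng.normal(np.log(5.0), 0.5)))
        if fam == "gaussian":
            w = (1.0, 0.0, 0.0)
        elif fam == "exponential":
            w = (0.0, 1.0, 0.0)
        elif fam == "zero_spike":
            w = (0.0, 0.0, 1.0)
        else:
            raw = rng.dirichlet([3, 2, 1])
            w = tuple(raw / raw.sum())
        specs.append(GeneSpec(f"G{i:05d}", fam, w, mu=mu, sigma=sigma, rate=rate))
    return specs, truth


def _sample_gene(spec: GeneSpec, condition: int, n: int, rng: np.random.Generator,
                 latent: np.ndarray | None = None, loading: float = 0.0) -> np.ndarray:
    w, mu, sigma, rate = spec.params_for(condition)
    comp = rng.choice(3, size=n, p=w)
    x = np.empty(n)
    g = comp == 0
    if g.any():
        eps = rng.standard_normal(g.sum())
        if latent is not None and loading != 0:
            z = loading * latent[g] + np.sqrt(1 - loading**2) * eps
        else:
            z = eps
        x[g] = mu + sigma * z
    e = comp == 1
    if e.any():
        x[e] = rng.exponential(1.0 / rate, size=e.sum())
    u = comp == 2
    if u.any():
        x[u] = rng.uniform(0.0, 1.0, size=u.sum())
    return np.clip(x, 0.0, None)  # expression is non-negative


def simulate_pair(
    config: CohortConfig,
    specs: list[GeneSpec] | None = None,
    truth: SyntheticTruth | None = None,
    condition_names: tuple = ("WT", "mutant"),
) -> tuple[ExpressionMatrix, ExpressionMatrix, SyntheticTruth]:
    """Simulate a matched WT/mutant pair with planted DV/DE/module structure.

    If ``specs`` is omitted a default panel is built from the config (see
    :func:`default_gene_specs`).  The same seed always yields bit-identical
    matrices.
    """
    rng = np.random.default_rng(config.seed)
    if specs is None:
        specs, truth = default_gene_specs(config, rng=rng)
    elif truth is None:
        truth = SyntheticTruth(
            dv_gene_ids={s.gene_id for s in specs if s.condition_effect in ("variance_shift", "gaussian_fraction_shift")},
            de_gene_ids={s.gene_id for s in specs if s.condition_effect == "mean_shift"},
        )
        for s in specs:
            if s.condition_effect in ("variance_shift", "gaussian_fraction_shift"):
                truth.dv_direction[s.gene_id] = (
                    "more_variable_mutant" if s.condition_effect == "gaussian_fraction_shift" or s.effect_magnitude > 1
                    else "more_variable_wt"
                )
    if len(specs) != config.n_genes:
        raise ValueError(f"expected {config.n_genes} gene specs, got {len(specs)}")

    n = config.n_cells_per_condition
    module = truth.module_gene_ids
    mats = []
    for cond in (0, 1):
        latent = rng.standard_normal(n)
        loading = config.module_corr_by_condition[cond]
        arr = np.empty((len(specs), n))
        for i, spec in enumerate(specs):
            in_module = spec.gene_id in module
            arr[i] = _sample_gene(spec, cond, n, rng,
                                  latent=latent if in_module else None,
                                  loading=loading if in_module else 0.0)
        name = condition_names[cond]
        cells = [f"{name}_c{j:04d}" for j in range(n)]
        values = pd.DataFrame(arr, index=[s.gene_id for s in specs], columns=cells)
        meta = pd.DataFrame(
            {
                "subject": f"{name}_S1",
                "condition": name,
                "cell_type": "NPC",
                "aligned_read_count": 1e6,
                "genes_detected_fraction": (arr > 0).mean(axis=0),
            },
            index=values.columns,
        )
        mats.append(ExpressionMatrix(values, meta))
    return mats[0], mats[1], truth


def simulate_cohort(
    config: CohortConfig,
    specs: list[GeneSpec] | None = None,
    group_names: tuple = ("healthy", "disease"),
) -> tuple[list[ExpressionMatrix], list[str]]:
    """Simulate per-subject matrices for two groups of subjects.

    All subjects share the same gene panel; subjects of group 2 receive the
    second entry of ``zero_inflation_by_group`` as extra dropout, and every
    cell's profile is scaled by a log-uniform depth factor from
    ``depth_range`` before dropout.  Returns the per-subject matrices and the
    parallel list of group labels.
    """
    rng = np.random.default_rng(config.seed)
    if specs is None:
        specs, _ = default_gene_specs(config, rng=rng)
    matrices: list[ExpressionMatrix] = []
    labels: list[str] = []
    lo, hi = config.depth_range
    n = config.n_cells_per_condition
    for group, name in enumerate(group_names):
        dropout = config.zero_inflation_by_group[group]
        for s in range(config.n_subjects_per_group):
            arr = np.empty((len(specs), n))
            for i, spec in enumerate(specs):
                arr[i] = _sample_gene(spec, 0, n, rng)
            depth = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
            arr *= depth[None, :]
            if dropout > 0:
                arr[rng.random(arr.shape) < dropout] = 0.0
            subject = f"{name}_S{s:02d}"
            cells = [f"{subject}_c{j:04d}" for j in range(n)]
            values = pd.DataFrame(arr, index=[sp.gene_id for sp in specs], columns=cells)
            meta = pd.DataFrame(
                {"subject": subject, "condition": name, "cell_type": "neuron"},
                index=values.columns,
            )
            matrices.append(ExpressionMatrix(values, meta))
            labels.append(name)
    return matrices, labels


def write_pair(m_wt: ExpressionMatrix, m_mut: ExpressionMatrix, truth: SyntheticTruth,
               outdir: str | Path, format: str = "tsv") -> None:
    """Write a simulated pair (matrices, metadata, truth table) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = {"tsv": "tsv", "csv": "csv", "mtx": "mtx"}[format]
    for name, m in (("wt", m_wt), ("mut", m_mut)):
        write_matrix(m, outdir / f"{name}.{ext}", format)
        m.cell_meta.to_csv(outdir / f"{name}.meta.tsv", sep="\t")
    truth.write(outdir / "truth.tsv")
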