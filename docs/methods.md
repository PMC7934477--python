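# Methods

This note documents the statistical model behind `txhet`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions taken where the design was open.

## Setting and assumptions

The package analyses a genes × cells matrix of non-negative, normalized
expression values (quantile-normalized TPM-like units) for two conditions —
canonically a mutant line and its isogenic, gene-corrected control, so that
differences are attributable to the mutation rather than genetic background.
All statistics treat cells as exchangeable replicates of their condition;
there is no explicit model of cell-cycle phase, batch, or pseudotime. For
multi-subject (cohort) analyses the subject, not the cell, is the unit of
replication.

## Quality control

Cells are filtered in a fixed order: (1) fewer than 2×10⁵ aligned reads,
(2) less than 15 % of genes detected (detected = value > 0; no expression
floor is imposed because normalized units make any fixed floor arbitrary),
(3) neural-to-embryonic marker index (NES + TUBB3)/(POU5F1 + NANOG) < 2 —
cells at exactly 2 are kept, 0/0 is flagged undefined and kept, x/0 with
x > 0 is +∞ and kept, (4) outlier removal: within each condition, each
cell's average Spearman correlation with all other cells is computed; cells
more than `mad_k` = 5 unscaled median-absolute-deviations *below* the median
are removed. The MAD carries no 1.4826 consistency factor (the threshold is
a convention, not an estimator of σ), and the filter is one-sided because
its purpose is to catch decorrelated outliers — a `mad_two_sided` flag
restores the symmetric reading. Whether the MAD stage should pool
conditions is genuinely open; per-condition is the default with
`mad_per_condition=False` available. Stages with missing inputs (no read
counts in the metadata, markers absent) are skipped with a recorded warning
rather than failing.

## Quantile normalization

Each cell's values are replaced by the across-cell mean of the sorted
profiles at the corresponding ranks, so every cell ends up with an identical
sorted vector. Ties within a cell receive the mean of the reference values
at the tied ranks; this keeps blocks of zeros at zero (the bottom reference
quantiles are zero whenever every cell has at least as many zeros).
On tie-free data the transform is exactly idempotent; with ties a second
application can shift tied groups by the tie-averaging, which in practice is
confined to the zero block and therefore a no-op there.

## Detection-median heterogeneity

Within each cell, genes are ranked ascending by expression (average ranks on
ties), so "largest average rank" selects the most highly expressed program.
The k genes with the largest across-cell average rank are taken (k = 200 by
default; 100 and 500–1000 are supported since small datasets warrant smaller
panels), each gene's detection fraction (cells with value > 0) is computed,
and the median over the k genes is the statistic. Because ranks are
invariant to any positive per-cell scaling, the statistic is insensitive to
sequencing depth — the property that motivates it. In multi-subject mode,
subjects contributing fewer than 50 cells are excluded and recorded. Groups
are compared with a one-sided Wilcoxon rank-sum test on per-subject values
(disease < healthy).

## Intra-condition distance

For every unordered pair of cells within a condition, 1 − Pearson r of their
expression profiles (range [0, 2]). The default gene filter — detected in
≥ 50 % of cells and mean > 5 normalized counts, applied jointly so a gene
must pass in *both* conditions — keeps the distance from being dominated by
dropout noise; an `all_genes` switch serves whole-transcriptome (droplet)
analyses. Condition comparison is a two-sample t-test on cell-pair
distances for isogenic pairs, or a rank-sum on per-subject medians for
cohorts; both are exposed because cell pairs within a condition are not
independent and the subject-level test is the conservative choice.

## Correlation structure

Gene-gene Spearman correlations per condition; a gene whose rank vector is
constant in either condition is degenerate (correlation undefined), flagged,
and excluded from summaries. Degeneracy is detected on the *ranks*, not on a
floating-point variance, so values equal up to rounding are treated as
constant. Each gene's average squared correlation excludes the diagonal
(including it would add a uniform 1/n to every gene). The squared-correlation
difference is oriented WT² − mutant², so positive values mean decorrelation
in the mutant.

The "declining cluster" runs k-means (k = 2, 6 internal restarts, max
10,000 iterations, 10 independent runs, best within-cluster sum of squares
wins) on the rows of the squared-correlation-difference matrix — each gene's
full difference profile, chosen over the scalar per-gene average because it
preserves which partners a gene lost. The returned cluster is the one with
the strongest mean correlation loss; `select="largest"` returns the biggest
cluster instead (the two coincide when decorrelation is genome-wide, as in
the disease systems this analysis targets, but only the signal-based rule
recovers a minority module). A silhouette below 0.1 flags the partition as
"no structure". Replicate error bars for the correlation-sd comparison use
10 subsamples of 80 % of cells without replacement, an equal number from
each condition; the resampling scheme is a free parameter since nothing
pins it down externally.

## Mixture model

Each gene's per-cell expression is modelled as

  f(x) = π_G · N(x; μ, σ) + π_E · λe^(−λx) (x ≥ 0) + π_U · 1[0 ≤ x ≤ 1],

five free parameters (π has two degrees of freedom; the uniform none). The
Gaussian captures the coherently expressed cell fraction, the exponential a
heavy low-expression tail, and the uniform the near-zero dropout spike.
The closed-form M-step is the model's practical advantage over
negative-binomial mixtures.

EM details: responsibilities from the three densities; M-step closed form
(π = mean responsibility, μ/σ Gaussian-weighted moments, λ = Σr_E/Σr_E·x);
σ floored at 10⁻³ × the data sd against singular Gaussians; observations
with zero density under all components get a uniform ε = 10⁻¹² so the
E-step stays defined; convergence at |Δ log L| < 10⁻⁸ or 1,000 iterations;
5 restarts (one moment-based: μ, σ from values > 1, λ from the reciprocal
mean of values in (0, median]; the rest randomly perturbed), best final
log-likelihood wins. Fits run on the quantile-normalized scale, where the
U(0, 1) component matches the near-zero spike; a `rescale` flag (divide by
the max) is available for data on other scales. Genes with fewer than 20
cells are refused; all-constant genes return a flagged degenerate fit.

Classification: π_G > 0.9 pure Gaussian, π_G < 0.8 low Gaussian (zero
spike and/or extreme values), otherwise mixed; boundaries are strict, so
π_G = 0.9 is mixed.

## Differential variability

*Similar-mean filter.* Genes detected in ≥ 50 % of cells with mean > 5 in
both conditions and |mean-difference index| strictly below 0.05 (the index,
not the equivalent ~10 % ratio, is the authoritative cutoff; 0.1 is the
supported sensitivity setting).

*Model-based (DVSM) calls.* Two pure Gaussians → type I: 10,000 bootstrap
resample pairs, mutant/WT sd ratio each, percentile CI (the simplest scheme
consistent with plain resampling; coverage at n = 100 is ≈ 93–95 %, slightly
anti-conservative, as the acceptance checks measure). CI entirely above
(below) 1 → more variable in the mutant (WT). Pure Gaussian vs π_G < 0.8 →
type II call for the mixed condition — its distribution has acquired zeros
and/or extreme values. A pure Gaussian against a borderline π_G ∈ [0.8, 0.9]
is not classifiable and returns not-applicable, as do unconverged fits.

*Trimmed CV.* sd/mean after deleting floor(n·0.05), at least 1, values from
each tail — one or two extreme cells can otherwise double a CV estimate.
The CV-based DVSM call combines a bootstrap CI on the trimmed-CV ratio with
a permutation test that shuffles condition labels and recomputes |log CV
ratio| (two-sided, resolution 1/(n_perm + 1)); BH correction across genes
is applied at the table level.

*Variability rank score.* Genes sorted by mean; within every window of 150
consecutive genes (stride 1) the trimmed CVs are ranked (average ranks on
ties) and rescaled to [0, 1]; a gene's score is the mean over the windows
containing it. Genes within window − 1 of either extreme belong to fewer
windows and are dropped. The minimum panel is 2·window − 1 genes (the
smallest size at which any gene attains full window membership). The score
is rank-based within windows, hence invariant to monotone transforms of the
CV and empirically uncorrelated with the mean even when the raw CV carries a
1/√mean trend. Window width 150 trades locality in mean against rank
resolution; it is configurable.

*DV calls.* The score difference (mutant − WT) is compared to its own
distribution: genes deviating from the mean difference by more than 1 or 2
sd are DV, direction by sign. A zero-sd difference distribution (identical
inputs) yields no calls by construction.

*Differential expression.* Per condition a = mean(log2(x + 1)); DE requires
a_wt + a_mut > 3, |a_mut − a_wt| ≥ 1 (2-fold), and BH-adjusted p < 0.05
from a two-sided rank-sum test — chosen as default because it is valid
across all three mixture shapes; Welch's t-test is available by flag.

*Enrichment.* Exact upper-tail hypergeometric p on the overlap between a
query set and an annotation set, with the expressed-gene background as the
universe and BH across annotation sets.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:
per-gene distributions drawn from the same three families the mixture model
fits (Gaussian, exponential, uniform-on-(0,1) zero spike) and their
mixtures, on a TPM-like scale (log-normal means around 20, CVs 0.15–0.45);
negative Gaussian draws are truncated at 0, mirroring non-negative
normalized data. Planted condition effects: `variance_shift` multiplies σ
by the effect size (2 by default) with the population mean identical by
construction — variance-shift genes use CV ≤ 0.15 so truncation at zero is
negligible and the equal-mean guarantee holds in samples; 
`gaussian_fraction_shift` moves Gaussian weight (0.4 by default) into the
other components (a type-II signature); `mean_shift` scales the expression
level (4-fold by default, a clear DE signal at ~100 cells). A co-expression
module is driven by one shared standard-normal latent factor per cell with
per-condition loading ℓ, giving pairwise gene correlations ≈ ℓ² while total
per-gene variance is held fixed — decorrelation without a variance
confound. Cohort mode adds per-cell depth factors (log-uniform over a
16-fold range, echoing the orders-of-magnitude read-depth spread of plate
data) and per-group Bernoulli dropout; the default (0, 0.4) contrast drives
the detection-median separation between groups. Marker genes (NES/TUBB3 and
POU5F1/NANOG analogues) are planted for the QC stage.

Not emulated: UMI counting noise, read-level error, batch effects beyond
depth/dropout, cell-type mixtures, mean-variance coupling beyond the
configured CVs, and any empirical joint distribution of depth and dropout —
both are free parameters because no external estimate of their joint law is
available. Passing tests on this generator therefore demonstrate correctness
of the statistics and recovery of planted structure under the model's own
assumptions, not robustness to every artifact of real droplet chemistry.

## Problem sizes, determinism, degenerate inputs

The test-suite and acceptance runs use deliberately modest sizes — hundreds
of genes, 80–200 cells per condition, hundreds of resampling replicates for
calibration loops (the full 10,000-replicate defaults remain the analysis
defaults) — chosen so the whole verification runs in minutes on one CPU
while keeping Monte-Carlo error well inside the asserted margins.

One pipeline seed governs everything; per-gene resampling substreams are
derived as (seed·100003 + gene index) mod 2³¹−1, so results are independent
of iteration order and identical configs give byte-identical outputs.
Degenerate situations are handled explicitly rather than by exception:
constant genes (flagged, excluded from correlation summaries; CV 0; EM
degenerate fit), zero trimmed means (NaN, call not-applicable), zero-sd DV
difference distributions (no calls), empty gene filters (error naming the
filter), and t-tests on zero-variance distances (fall back to rank-sum with
a warning).

## Known limitations

- The mixture likelihood is multimodal; 5 restarts make misconvergence rare
  but not impossible for pathological shapes.
- Percentile bootstrap CIs on spread ratios run ~1–2 points below nominal
  coverage at n = 100; BCa would be closer at ~3× the cost.
- Cell-pair distances within a condition are dependent, so the t-test on
  them overstates significance; the subject-median rank-sum is the
  defensible test for cohort claims.
- The rank score requires ≥ 2·window − 1 genes after filtering and silently
  reflects whatever mean-CV coupling survives inside a window.
- k-means on the squared-correlation-difference rows assumes one dominant
  declining block; overlapping modules will be merged or split.
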