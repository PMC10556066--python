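# Methods

This note documents the models, parameter choices and numerical conventions
behind `blastsig`, and what the synthetic experiments do and do not
demonstrate.

## Synthetic data model

Single-cell counts follow a gamma–Poisson (negative binomial) model. Each
gene g has a relative abundance w_g drawn log-normal(μ=1, σ=1) on the count
scale — heavy-tailed, like real scRNA-seq libraries. A cell with library
size L and abundance vector w has counts X_g ~ NB(mean = L·w_g/Σw, size = θ)
with θ = 10 by default: droplet UMI counts are close to Poisson, and θ = 10
adds the mild extra-Poisson noise typically seen per gene.

Seven planted marker genes emulate blast-restricted progenitor markers.
Their baseline is parameterized as `planted_base_count` (default 0.08
expected counts per non-blast cell at the mean library size), which keeps
their detection below ~10% of non-blast cells regardless of the size of the
gene universe — the "no or very low expression outside blasts" regime of
genuine markers. Blast cells multiply the planted abundances by 2^lfc with
lfc = (3.0, 3.0, 2.9, 2.9, 2.8, 2.8, 1.5): six strong markers at the top of
the plausible range plus one borderline marker that the specificity filters
are expected to reject (a mean-ratio cap of 0.25 requires log2 FC above 2).
Each patient additionally shifts every gene of its blast cells by
N(0, patient_sd²) in log2 (default 0.3). This patient random effect is what
makes the single-cell DE stage return ~100–200 "significant" genes of which
only the planted handful are real markers — the funnel's raison d'être.

Blast cells draw their library size as `blast_libsize_factor` (default 2.0)
times the uniform (1,000–5,000) non-blast draw. Malignant blasts are
hypertranscriptional — they carry substantially more RNA than differentiated
marrow cells — and this property matters quantitatively: without it, the
off-target detection cap bounds the per-cell counting statistics of the
markers so hard that even the Bayes-optimal classifier on the panel tops out
near AUC 0.95, below the regime the discovery method operates in.
Mitochondrial genes (symbol prefix `MT-`, 1% of the universe) get an 8×
abundance boost and a per-cell log-normal load jitter (σ = 0.5) so that a
small tail of stressed cells genuinely exceeds the 25% QC threshold.

Bulk samples are mixtures: expected expression b·blast + (1−b)·normal at a
fixed sequencing depth of 10⁶ counts, with the same NB noise. Blast
fractions are Uniform(0, 1) for diagnosis samples; the last 24 of the
124-sample default cohort are end-of-induction samples with b ≤ 0.05
(post-therapy marrow is at most minimal residual disease — matching the use
of post-induction samples as the low-blast comparator rather than a separate
expression profile). The analytic population profiles (with the patient
effect integrated out, E[2^δ] = exp((σ ln2)²/2)) are exposed by
`expression_profiles` and double as the oracle for generator tests.

Survival times are exponential with hazard λ₀·exp(β·z), λ₀ = ln 2 (median
survival one time unit at the cohort-average score), β = `survival_beta` per
SD of the score. Censoring is independent: with probability `censor_rate` a
sample is censored at a uniform fraction of its event time, giving exactly
the requested censoring rate.

What the generator does **not** emulate: doublets, ambient RNA, UMI
saturation, batch chemistry, cell-type substructure beyond blast/non-blast,
gene–gene correlation, and isoform effects. Passing tests therefore show
that the pipeline recovers planted structure under realistic count noise and
patient heterogeneity — not that it is robust to every artifact of real
droplet data.

## Discovery funnel

Stage 1 (single-cell DE) uses the Wilcoxon rank-sum test per gene between
blast and non-blast cells on log-normalized expression
(log(1 + 10⁴·c/L), natural log). Exact enumeration is used when both groups
have ≤ 10 cells and the gene is tie-free; otherwise the normal approximation
with tie-corrected variance and continuity correction. Fold change is the
ratio of de-logged group means with pseudocount 10⁻⁹ (the FC scale is a
linear ratio; natural-log and log2 readings of the same threshold are
exposed via configuration). Benjamini–Hochberg controls the FDR across
genes. Thresholds: FC > 1.2, adjusted P < 0.01.

Stage 2 bins the bulk cohort by clinical blast percentage — high (>60,
strict), mid ([30, 60], closed), low (<30, strict), and post-induction — and
keeps genes with FC > 1.8 and Welch t-test P < 0.03 (high vs post-induction)
and P < 0.04 (high vs low) on log2(CPM+1). Raw p-values are used (the
multiplicity of this stage is absorbed by the FC filter and the preceding
FDR-controlled stage). voom precision weights are not reproduced; t-tests on
log2-CPM capture the filter's intent.

Stage 3 removes candidates detected in more than 10% of non-blast cells or
whose non-blast/blast mean ratio exceeds 0.25 — the operationalization of
"filter genes expressed in the normal marrow microenvironment". Both
thresholds are configuration fields.

Stage 4 ranks survivors by linear SVM-RFE: within each training fold of a
repeated stratified 5-fold scheme (10 repeats), features are z-standardized
on the training data, a linear SVM (scikit-learn `LinearSVC`, primal,
C = 1) is fitted, and the smallest-|weight| feature is removed iteratively
down to five. Per-fold ranks (survivors ordered by final |weight|,
eliminated features by round) are averaged into the aggregate ranking. For
every panel size in 5–15, each fold's own top genes are refitted and scored
out-of-fold; the final panel is the smallest size whose mean AUC is within
`auc_tolerance` = 0.005 of the best. Repeated stratified k-fold is used as
the standard equivalent of the out-of-bag scheme the original description
names; cells (not patient pseudobulk) are the classification units.

## Scoring

The module score bins genes into 24 equal-frequency bins of mean expression
and samples 100 control genes per set gene from the matching bin (with
replacement when the bin is small), excluding set genes; the score is the
set-mean minus control-mean per cell. The translation invariance (adding c
to every set gene adds c to every score) holds exactly when the shift does
not move set genes between bins.

ssGSEA ranks a unit's genes by expression (ascending midranks, so the
highest-expressed gene carries the largest weight and ties share one) and
sums, over the descending-expression ordering, the difference between the
rank^α-weighted ECDF of in-set genes and the plain ECDF of out-of-set genes
(α = 0.25, running sum unnormalized by default; both configurable).

The combined z-score (Lee et al. style) z-scores each gene across samples
(ddof = 1) and reports Σ z_g/√k per sample, so duplicating a gene k times
scales a single-gene score by √k, and column means vanish by construction.
Gene-symbol matching is case-sensitive and exact; an alias hook exists but
is empty. The bundled effector-T set retains the symbol `NFACT1` verbatim
from its printed source (the exhausted-T set uses `NFATC1`); the library
warns rather than silently merging them.

## Copy-number burden

The caller is deliberately minimal: per-gene log2 expression minus the
reference mean, smoothed along genomic order by a centered, edge-truncated
moving average of 101 genes within each chromosome, median-centered per cell
and clipped to ±3. A chromosome is "altered" for a cell when |mean residual|
exceeds 0.2 log2 — low enough to call a clonal single-copy gain (~+0.58) or
loss (~−1), high enough to ignore counting noise when chromosomes carry
dozens of adequately expressed genes. An adaptive alternative (3× the MAD of
reference-vs-reference chromosome means) is provided. The burden metric
counts altered autosomes excluding chromosome 6, whose apparent alterations
track HLA expression differences rather than true copy number; the range is
therefore 0–21. No HMM state calling, subclustering or denoising bands are
attempted — the burden metric, not the caller, is the point. The planted
chr7-gain experiments use log-CPM normalization and well-covered cells
because the log1p pseudocount otherwise attenuates a true doubling below
+1 log2 on sparse counts; the sparse-gene tail is assumed filtered, as CNA
callers do.

## Survival statistics

Kaplan–Meier, the log-rank test and univariate Cox regression (Efron ties)
are delegated to `lifelines`; both two-sided and directional one-sided
log-rank p-values are reported because figure conventions vary. The optimal
cutpoint uses per-subject log-rank (Savage) scores: for candidate c (high =
score > c, both sides ≥ 10% of samples), the standardized statistic is
S_k/√(σ²k(n−k)/(n−1)) with S_k the low-side score sum and σ² = Σe²/(n−1);
the cutpoint maximizes |Z|. The selection-corrected p-value is the
Brownian-bridge supremum bound 2Σ(−1)^{j+1}exp(−2j²q²) with
q = |S|/√(σ²(n−1)) (the Contal–O'Quigley construction behind
martingale-residual cutpoint estimators), floored at the uncorrected normal
p so the correction never reports less evidence than no correction. Median
splits assign ties to the low group (configurable).

## LSC6 risk validation

The LSC6 score is Σ c_g·x_g over the six stemness genes on log2(x+1)
expression. The published coefficients belong to the score's original
derivation and are deliberately **not** bundled: they must be supplied, and
all tests use arbitrary documented weights. Risk bins follow the printed
boundaries: low < 0.95 ≤ medium < 1.9 ≤ high. Between-bin comparisons of
immune ssGSEA scores use the rank-sum (Mann–Whitney) test — the groups are
independent, so the signed-rank test sometimes named in this context does
not apply; bins with fewer than three samples are skipped with a warning.

## Problem sizes and design choices

The default study conditions — 3,000 cells (1,500/1,500) from three
patients over 2,000 genes, a 124-sample bulk cohort (100 diagnosis, 24
post-induction), survival cohorts of 124–300 samples, CNA populations of
60–200 cells over 1,980 genes — were chosen as the desk-scale analogue of
the motivating study design and are used consistently by the test-suite and
the acceptance script. Calibration experiments use 100–200 replicates. The
generator's operating point (marker strengths, baseline detection, blast
library factor) was fixed once, during design, so that the discovered
panel's cross-validated AUC sits in the high-0.9s regime where such
signatures are reported to operate; it is not adjusted per run.

## Known limitations

* The SVM surrogate (`LinearSVC`, squared hinge, primal) is not the exact
  maximum-margin dual solver; for these panel sizes the rankings agree, and
  determinism is exact.
* The ssGSEA tie convention (stable descending sort with ascending
  midrank weights) matches the in-package oracle; other implementations
  order ties differently and can differ in the last decimal places.
* The off-target filter's two thresholds encode an unstated down-selection
  step; both are exposed in `DiscoveryConfig` rather than hidden.
* The corrected cutpoint p-value is an asymptotic supremum bound; for very
  few events it is conservative.
* `module_score` needs a gene universe large enough for its 24 expression
  bins to contain informative control pools; on toy matrices with tens of
  genes the control noise dominates.
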