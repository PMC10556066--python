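"""Synthetic single-cell, bulk-cohort, and survival data with known ground truth.

The generator emulates the statistical structure that the blast-signature
discovery funnel assumes: a bone-marrow-like mixture of malignant blast
cells and differentiated non-blast cells in which a small panel of marker
genes is overexpressed by blasts only; bulk samples that are mixtures of a
blast and a normal expression profile at known blast fractions; and survival
times whose hazard depends on a per-sample enrichment score.

Counts follow a gamma-Poisson (negative binomial) model.  Baseline gene
abundances are log-normal (heavy-tailed, like real scRNA-seq); planted
marker genes are given a low, blast-restricted baseline so that they behave
like the lineage-restricted progenitor markers the analysis is designed to
find (near-silent in the normal microenvironment, switched on in blasts).
Each patient contributes gene-wise log-normal shifts to its blast cells,
which reproduces the patient-specific blast heterogeneity of real AML and
feeds realistic false positives into the single-cell DE stage.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "SimConfig",
    "generate_single_cell",
    "expression_profiles",
    "generate_bulk_cohort",
    "generate_survival",
    "BulkCohort",
    "write_mtx_dir",
    "read_mtx_dir",
]

#: default planted marker panel (the blast-restricted progenitor genes the
#: funnel is expected to recover)
DEFAULT_PLANTED = ("CLEC11A", "PRAME", "AZU1", "NREP", "ARMH1", "C1QBP", "TRH")

#: default per-gene blast overexpression, log2 units.  Six near-exclusive
#: strong markers (real blast markers are close to blast-restricted, so they
#: sit at the strong end of the plausible range) plus one borderline marker
#: at the weak end, which the specificity filters are expected to lose: the
#: off-target rule (non-blast/blast mean ratio <= 0.25) requires log2 FC
#: above 2.
DEFAULT_LOG2FC = (3.0, 3.0, 2.9, 2.9, 2.8, 2.8, 1.5)

# Rough autosome lengths (Mb), used only to spread genes over chromosomes in
# realistic proportions for the CNA residual pipeline.
_AUTOSOME_MB = np.array(
    [248, 242, 198, 190, 182, 171, 159, 145, 138, 134, 135, 133,
     114, 107, 102, 90, 83, 80, 59, 64, 47, 51],
    dtype=float,
)


@dataclasses.dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults describe the desk-scale study conditions used throughout the
    test-suite: 3,000 cells (half blast, half non-blast) from three patients
    over a 2,000-gene universe with seven planted blast markers, and a
    124-sample bulk cohort (100 diagnosis + 24 end-of-induction samples).
    """

    n_genes: int = 2000
    n_blast_cells: int = 1500
    n_nonblast_cells: int = 1500
    n_patients: int = 3
    planted_genes: Sequence[str] = DEFAULT_PLANTED
    planted_log2fc: Sequence[float] = DEFAULT_LOG2FC
    #: expected baseline counts of each planted gene per non-blast cell at
    #: the mean library size.  The default keeps detection in <10% of
    #: non-blast cells — the "no or very low expression outside blasts"
    #: regime of genuine blast-restricted markers — independently of the
    #: size of the gene universe.
    planted_base_count: float = 0.08
    patient_sd: float = 0.30          # per-patient gene-wise random effect, log2
    nb_dispersion: float = 10.0       # NB size parameter; var = mu + mu^2/size
    libsize_range: tuple[float, float] = (1000.0, 5000.0)
    #: malignant blasts are hypertranscriptional: their expected library size
    #: is this multiple of the non-blast draw from ``libsize_range``
    blast_libsize_factor: float = 2.0
    mito_gene_fraction: float = 0.01
    mito_boost: float = 8.0           # relative abundance boost of MT- genes
    mito_cell_sigma: float = 0.5      # per-cell log-normal jitter of mito load
    n_bulk_samples: int = 124
    n_bulk_eoi: int = 24
    bulk_libsize: float = 1.0e6
    blast_fraction_range: tuple[float, float] = (0.0, 1.0)
    survival_beta: float = 1.0        # log-hazard per SD of enrichment score
    censor_rate: float = 0.2
    seed: int = 17

    def __post_init__(self) -> None:
        if len(self.planted_genes) != len(self.planted_log2fc):
            raise ValueError("planted_genes and planted_log2fc lengths differ")
        if any(f < 0 for f in self.planted_log2fc):
            raise ValueError("planted_log2fc must be non-negative")
        for name, v in [
            ("n_genes", self.n_genes),
            ("n_blast_cells", self.n_blast_cells),
            ("n_nonblast_cells", self.n_nonblast_cells),
            ("n_patients", self.n_patients),
            ("n_bulk_samples", self.n_bulk_samples),
        ]:
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        lo, hi = self.blast_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("blast_fraction_range must lie within [0, 1]")
        if not (0.0 <= self.censor_rate <= 1.0):
            raise ValueError("censor_rate must lie within [0, 1]")
        if self.n_bulk_eoi >= self.n_bulk_samples:
            raise ValueError("n_bulk_eoi must be smaller than n_bulk_samples")


def _gene_universe(config: SimConfig) -> pd.DataFrame:
    """Deterministic gene table: symbols, mito flags, genomic annotation.

    Planted genes are spread evenly through the universe (so they land on
    different chromosomes); mitochondrial genes carry the conventional
    ``MT-`` prefix so QC can find them.
    """
    n = config.n_genes
    n_mito = int(round(config.mito_gene_fraction * n))
    planted = list(config.planted_genes)
    if len(planted) != len(set(planted)):
        raise ValueError("planted_genes contains duplicates")
    if len(planted) + n_mito > n:
        raise ValueError("n_genes too small for planted and mitochondrial genes")

    symbols = np.array([f"G{i + 1:05d}" for i in range(n)], dtype=object)
    # planted genes at evenly spaced positions
    planted_pos = np.linspace(0, n - n_mito - 1, num=len(planted), dtype=int)
    symbols[planted_pos] = planted
    # mitochondrial genes at the tail: real MT genes live on the
    # mitochondrial genome, outside the 22 autosomes used by the CNA module
    mito_pos = np.arange(n - n_mito, n)
    symbols[mito_pos] = [f"MT-S{i + 1}" for i in range(n_mito)]

    is_mito = np.zeros(n, dtype=bool)
    is_mito[mito_pos] = True
    is_planted = np.zeros(n, dtype=bool)
    is_planted[planted_pos] = True

    # chromosomes proportional to autosome length; mito genes get chromosome 0
    # (ignored by the CNA pipeline)
    n_auto = n - n_mito
    weights = _AUTOSOME_MB / _AUTOSOME_MB.sum()
    per_chrom = np.floor(weights * n_auto).astype(int)
    per_chrom[: n_auto - per_chrom.sum()] += 1
    chromosome = np.zeros(n, dtype=int)
    chromosome[:n_auto] = np.repeat(np.arange(1, 23), per_chrom)
    start = np.zeros(n, dtype=int)
    for c in range(1, 23):
        idx = np.where(chromosome == c)[0]
        start[idx] = (np.arange(len(idx)) + 1) * 100_000

    return pd.DataFrame(
        {
            "symbol": symbols,
            "mt": is_mito,
            "planted": is_planted,
            "chromosome": chromosome,
            "start": start,
        }
    ).set_index("symbol", drop=False)


def _baseline_weights(config: SimConfig, genes: pd.DataFrame,
                      rng: np.random.Generator) -> np.ndarray:
    """Relative count-scale abundances: log-normal(mu=1, sigma=1) baseline.

    Planted genes get the weight that yields ``planted_base_count`` expected
    counts per non-blast cell at the mean library size, whatever the size of
    the gene universe.
    """
    w = rng.lognormal(mean=1.0, sigma=1.0, size=config.n_genes)
    planted = genes["planted"].to_numpy()
    w[genes["mt"].to_numpy()] *= config.mito_boost
    mean_lib = 0.5 * (config.libsize_range[0] + config.libsize_range[1])
    c, k = config.planted_base_count, int(planted.sum())
    rest = w[~planted].sum()
    if mean_lib <= c * k:
        raise ValueError("planted_base_count too large for the library size")
    w[planted] = c * rest / (mean_lib - c * k)
    return w


def _nb_counts(mu: np.ndarray, size: float, rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson draw with mean ``mu`` and NB size parameter ``size``."""
    lam = rng.gamma(shape=size, scale=np.maximum(mu, 1e-300) / size)
    return rng.poisson(lam)


def generate_single_cell(config: SimConfig,
                         gene_names: Sequence[str] | None = None) -> ad.AnnData:
    """Simulate a blast / non-blast single-cell count matrix.

    Returns an :class:`anndata.AnnData` with raw counts in ``X``, cell
    metadata (``patient``, ``timepoint``, ``outcome``, ``label``,
    ``mito_fraction``) in ``obs`` and genomic annotation (``chromosome``,
    ``start``, ``mt``) in ``var``.  The generative ground truth (baseline
    weights, planted log2 fold changes, per-patient shifts) is stored under
    ``uns['truth']`` so tests can use analytic expectations as oracles.

    Blast cells are diagnosis (Dx) cells; non-blast cells are split between
    Dx and end-of-induction (EOI), mirroring the clinical sampling design in
    which post-therapy marrow is dominated by differentiated cells.
    Deterministic given ``config.seed``.
    """
    genes = _gene_universe(config)
    if gene_names is not None:
        gene_names = list(gene_names)
        if len(gene_names) != config.n_genes:
            raise ValueError("gene_names length must equal n_genes")
        missing = [g for g in config.planted_genes if g not in set(gene_names)]
        if missing:
            raise ValueError(
                f"planted gene(s) absent from gene universe: {', '.join(missing)}"
            )
        genes = genes.copy()
        genes["symbol"] = gene_names
        genes = genes.set_index("symbol", drop=False)
        genes["planted"] = genes.index.isin(config.planted_genes)
        genes["mt"] = genes.index.str.startswith("MT-")

    rng = np.random.default_rng([config.seed, 0])
    w = _baseline_weights(config, genes, rng)
    lfc = np.zeros(config.n_genes)
    planted_idx = np.where(genes["planted"].to_numpy())[0]
    # map planted effect sizes onto universe order of planted genes
    order = {g: i for i, g in enumerate(config.planted_genes)}
    for j in planted_idx:
        lfc[j] = config.planted_log2fc[order[genes.index[j]]]

    # per-patient gene-wise shifts (applied to blast cells only)
    shifts = rng.normal(0.0, config.patient_sd,
                        size=(config.n_patients, config.n_genes))

    n_cells = config.n_blast_cells + config.n_nonblast_cells
    labels = np.array(["blast"] * config.n_blast_cells
                      + ["non-blast"] * config.n_nonblast_cells)
    patient = np.arange(n_cells) % config.n_patients
    timepoint = np.where(
        labels == "blast",
        "Dx",
        np.where(np.arange(n_cells) % 2 == 0, "Dx", "EOI"),
    )
    outcome_by_patient = np.array(
        ["relapse" if p % 2 == 0 else "CCR" for p in range(config.n_patients)]
    )

    lo, hi = config.libsize_range
    libsize = rng.uniform(lo, hi, size=n_cells)
    libsize[labels == "blast"] *= config.blast_libsize_factor
    # per-cell mitochondrial load jitter: real droplets vary widely in mito
    # content, and stressed/dying cells push past the QC threshold
    mito_scale = rng.lognormal(0.0, config.mito_cell_sigma, size=n_cells)
    mito_cols = genes["mt"].to_numpy()

    def _group_counts(sel: np.ndarray, w_group: np.ndarray) -> np.ndarray:
        W = np.broadcast_to(w_group, (int(sel.sum()), config.n_genes)).copy()
        W[:, mito_cols] *= mito_scale[sel, None]
        probs = W / W.sum(axis=1, keepdims=True)
        mu = libsize[sel, None] * probs
        return _nb_counts(mu, config.nb_dispersion, rng)

    counts = np.empty((n_cells, config.n_genes), dtype=np.int64)
    blast_mask = labels == "blast"
    for p in range(config.n_patients):
        sel = blast_mask & (patient == p)
        if sel.any():
            counts[sel] = _group_counts(sel, w * np.exp2(lfc + shifts[p]))
    counts[~blast_mask] = _group_counts(~blast_mask, w)

    totals = counts.sum(axis=1)
    mito_counts = counts[:, genes["mt"].to_numpy()].sum(axis=1)
    mito_fraction = np.divide(mito_counts, totals, out=np.zeros(n_cells),
                              where=totals > 0)

    obs = pd.DataFrame(
        {
            "patient": [f"P{p + 1}" for p in patient],
            "timepoint": timepoint,
            "outcome": outcome_by_patient[patient],
            "label": labels,
            "mito_fraction": mito_fraction,
        },
        index=[f"cell{i + 1:05d}" for i in range(n_cells)],
    )
    var = genes[["chromosome", "start", "mt", "planted"]].copy()

    adata = ad.AnnData(X=counts.astype(np.float64), obs=obs, var=var)
    adata.uns["truth"] = {
        "baseline_weight": w,
        "log2fc": lfc,
        "patient_shift": shifts,
        "planted_genes": list(config.planted_genes),
    }
    return adata


def expression_profiles(config: SimConfig) -> pd.DataFrame:
    """Analytic population expression profiles of the generative model.

    Returns per-gene relative abundances (columns ``blast`` and ``normal``,
    each summing to 1) marginalized over the patient random effect:
    E[2^delta] = exp((sd * ln 2)^2 / 2) for delta ~ N(0, sd^2) in log2 units.
    These are the profiles a bulk cohort drawn from the same population
    mixes, and they serve as the independent oracle for the empirical means
    of :func:`generate_single_cell`.
    """
    genes = _gene_universe(config)
    rng = np.random.default_rng([config.seed, 0])
    w = _baseline_weights(config, genes, rng)
    lfc = np.zeros(config.n_genes)
    planted_idx = np.where(genes["planted"].to_numpy())[0]
    order = {g: i for i, g in enumerate(config.planted_genes)}
    for j in planted_idx:
        lfc[j] = config.planted_log2fc[order[genes.index[j]]]
    patient_factor = np.exp(0.5 * (config.patient_sd * np.log(2.0)) ** 2)
    wb = w * np.exp2(lfc) * patient_factor
    return pd.DataFrame(
        {"blast": wb / wb.sum(), "normal": w / w.sum()},
        index=genes.index,
    )


@dataclasses.dataclass
class BulkCohort:
    """Bulk cohort: samples x genes expression plus per-sample metadata.

    ``meta`` columns: ``blast_pct`` (0-100, NaN allowed for non-Dx samples),
    ``timepoint`` (Dx/EOI), and optional ``os_time`` / ``os_event``.
    """

    expression: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.expression.index.equals(self.meta.index):
            raise ValueError("expression and meta must share the sample index")

    @property
    def n_samples(self) -> int:
        return self.expression.shape[0]

    def to_csv(self, path: str | Path) -> None:
        """Write the wide cohort table: metadata columns followed by genes."""
        wide = pd.concat([self.meta, self.expression], axis=1)
        wide.to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "BulkCohort":
        wide = pd.read_csv(path, index_col="sample_id")
        meta_cols = [c for c in ("blast_pct", "timepoint", "os_time", "os_event")
                     if c in wide.columns]
        return cls(expression=wide.drop(columns=meta_cols), meta=wide[meta_cols])


def generate_bulk_cohort(config: SimConfig,
                         blast_profile: np.ndarray | pd.Series,
                         normal_profile: np.ndarray | pd.Series) -> BulkCohort:
    """Simulate a bulk cohort as blast/normal mixtures at known blast fractions.

    Each diagnosis sample draws a blast fraction b ~ Uniform over
    ``config.blast_fraction_range``; expected expression is
    ``b * blast_profile + (1 - b) * normal_profile`` scaled to
    ``config.bulk_libsize``, with negative-binomial noise.  The last
    ``config.n_bulk_eoi`` samples are end-of-induction samples whose blast
    fraction is forced to at most 0.05 (post-therapy marrow is, at most,
    minimal residual disease).  ``blast_pct`` stores 100*b.
    """
    if isinstance(blast_profile, pd.Series) != isinstance(normal_profile, pd.Series):
        raise ValueError("profiles must both be Series or both arrays")
    if isinstance(blast_profile, pd.Series):
        if not blast_profile.index.equals(normal_profile.index):
            raise ValueError("profile gene indices differ")
        gene_index = blast_profile.index
        bp = blast_profile.to_numpy(dtype=float)
        np_ = normal_profile.to_numpy(dtype=float)
    else:
        bp = np.asarray(blast_profile, dtype=float)
        np_ = np.asarray(normal_profile, dtype=float)
        gene_index = pd.Index([f"G{i + 1:05d}" for i in range(bp.size)])
    if bp.shape != np_.shape:
        raise ValueError(
            f"profile length mismatch: {bp.shape[0]} vs {np_.shape[0]}"
        )
    bp = bp / bp.sum()
    np_ = np_ / np_.sum()

    rng = np.random.default_rng([config.seed, 1])
    n = config.n_bulk_samples
    n_eoi = config.n_bulk_eoi
    n_dx = n - n_eoi
    lo, hi = config.blast_fraction_range
    b = np.concatenate([
        rng.uniform(lo, hi, size=n_dx),
        rng.uniform(0.0, 0.05, size=n_eoi),
    ])
    timepoint = np.array(["Dx"] * n_dx + ["EOI"] * n_eoi)

    mix = b[:, None] * bp[None, :] + (1.0 - b)[:, None] * np_[None, :]
    mu = config.bulk_libsize * mix
    counts = _nb_counts(mu, config.nb_dispersion, rng)

    samples = pd.Index([f"S{i + 1:04d}" for i in range(n)], name="sample_id")
    expression = pd.DataFrame(counts, index=samples, columns=gene_index)
    meta = pd.DataFrame(
        {"blast_pct": 100.0 * b, "timepoint": timepoint}, index=samples
    )
    return BulkCohort(expression=expression, meta=meta)


def generate_survival(scores: np.ndarray | pd.Series,
                      config: SimConfig) -> pd.DataFrame:
    """Simulate survival times whose hazard depends on an enrichment score.

    Event times are exponential with hazard ``lambda0 * exp(beta * z)``,
    where ``z`` standardizes ``scores`` within the cohort and ``beta`` is
    ``config.survival_beta``; the baseline hazard is ln 2 (median survival of
    one time unit at the cohort-average score).  Censoring is independent:
    each sample is censored with probability ``config.censor_rate``, at a
    uniformly drawn fraction of its event time.  Returns a DataFrame with
    ``os_time`` and ``os_event`` columns.
    """
    s = pd.Series(scores).astype(float)
    if not np.isfinite(s.to_numpy()).all():
        raise ValueError("scores contain non-finite values")
    sd = s.std(ddof=0)
    z = (s - s.mean()) / sd if sd > 0 else s * 0.0

    rng = np.random.default_rng([config.seed, 2])
    lam = np.log(2.0) * np.exp(config.survival_beta * z.to_numpy())
    t = rng.exponential(1.0 / lam)
    censored = rng.uniform(size=len(s)) < config.censor_rate
    u = rng.uniform(size=len(s))
    time = np.where(censored, np.maximum(t * u, 1e-9), t)
    event = (~censored).astype(int)
    return pd.DataFrame({"os_time": time, "os_event": event}, index=s.index)


def write_mtx_dir(adata: ad.AnnData, outdir: str | Path) -> None:
    """Write a 10x-style MTX triplet plus cell metadata.

    Files: ``matrix.mtx`` (genes x cells, as 10x does), ``features.tsv``
    (symbol, chromosome, start), ``barcodes.tsv``, ``cell_meta.tsv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = scipy.sparse.csc_matrix(np.asarray(adata.X).T)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), mat, field="integer")
    feats = pd.DataFrame(
        {
            "symbol": adata.var_names,
            "chromosome": adata.var.get("chromosome", 0),
            "start": adata.var.get("start", 0),
        }
    )
    feats.to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    adata.obs.to_csv(outdir / "cell_meta.tsv", sep="\t")


def read_mtx_dir(indir: str | Path) -> ad.AnnData:
    """Read the triplet written by :func:`write_mtx_dir`."""
    indir = Path(indir)
    mat = scipy.io.mmread(str(indir / "matrix.mtx")).toarray().T.astype(float)
    feats = pd.read_csv(
        indir / "features.tsv", sep="\t", header=None,
        names=["symbol", "chromosome", "start"],
    )
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    var = feats.set_index("symbol", drop=False)
    var["mt"] = var.index.str.startswith("MT-")
    obs_path = indir / "cell_meta.tsv"
    if obs_path.exists():
        obs = pd.read_csv(obs_path, sep="\t", index_col=0)
        obs.index = obs.index.astype(str)
    else:
        obs = pd.DataFrame(index=barcodes.astype(str))
    adata = ad.AnnData(X=mat, obs=obs, var=var)
    adata.obs_names = barcodes.astype(str).to_numpy()
    return adata
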