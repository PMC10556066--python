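"""Quality control, normalization, and two-group differential expression.

Single-cell matrices are :class:`anndata.AnnData` objects with raw counts in
``X``.  QC follows the conventional thresholds for droplet data (mitochondrial
fraction, detected genes per cell, cells per gene); normalization is
library-size log-normalization; differential expression is the Wilcoxon
rank-sum test with Benjamini-Hochberg correction and a fold-change filter.
"""

from __future__ import annotations

import dataclasses
import warnings

import anndata as ad
import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = ["QCReport", "qc_filter", "lognormalize", "wilcoxon_de", "de_filter"]

_FC_EPS = 1e-9  # pseudocount on de-logged means when forming fold changes


@dataclasses.dataclass
class QCReport:
    n_cells_in: int
    n_genes_in: int
    n_cells_removed_mito: int
    n_cells_removed_genes: int
    n_genes_removed: int

    @property
    def n_cells_out(self) -> int:
        return self.n_cells_in - self.n_cells_removed_mito - self.n_cells_removed_genes

    @property
    def n_genes_out(self) -> int:
        return self.n_genes_in - self.n_genes_removed


def _mito_fraction(adata: ad.AnnData) -> np.ndarray:
    X = np.asarray(adata.X)
    totals = X.sum(axis=1)
    if "mt" in adata.var:
        mito = adata.var["mt"].to_numpy(dtype=bool)
    else:
        mito = adata.var_names.str.startswith("MT-").to_numpy()
    with np.errstate(invalid="ignore"):
        frac = np.divide(X[:, mito].sum(axis=1), totals,
                         out=np.zeros(adata.n_obs), where=totals > 0)
    return frac


def qc_filter(adata: ad.AnnData, max_mito: float = 0.25,
              min_genes_per_cell: int = 200,
              min_cells_per_gene: int = 3) -> tuple[ad.AnnData, QCReport]:
    """Remove low-quality cells, then rarely-detected genes.

    Cells are dropped when their mitochondrial count fraction exceeds
    ``max_mito`` or they detect fewer than ``min_genes_per_cell`` genes;
    genes expressed (count > 0) in fewer than ``min_cells_per_gene`` of the
    surviving cells are then dropped.  Returns a filtered copy and a report
    of removed counts.  Idempotent: re-applying the same thresholds to the
    output changes nothing.
    """
    if not (0.0 <= max_mito <= 1.0):
        raise ValueError("max_mito must lie in [0, 1]")
    if min_genes_per_cell < 0 or min_cells_per_gene < 0:
        raise ValueError("count thresholds must be non-negative")

    X = np.asarray(adata.X)
    mito_frac = _mito_fraction(adata)
    n_detected = (X > 0).sum(axis=1)

    bad_mito = mito_frac > max_mito
    bad_genes = (~bad_mito) & (n_detected < min_genes_per_cell)
    keep_cells = ~(bad_mito | bad_genes)
    if not keep_cells.any():
        raise ValueError("all cells removed by QC filtering")

    sub = adata[keep_cells].copy()
    cells_per_gene = (np.asarray(sub.X) > 0).sum(axis=0)
    keep_genes = cells_per_gene >= min_cells_per_gene
    report = QCReport(
        n_cells_in=adata.n_obs,
        n_genes_in=adata.n_vars,
        n_cells_removed_mito=int(bad_mito.sum()),
        n_cells_removed_genes=int(bad_genes.sum()),
        n_genes_removed=int((~keep_genes).sum()),
    )
    out = sub[:, keep_genes].copy()
    if out.n_vars == 0:
        raise ValueError("all genes removed by QC filtering")
    out.obs["mito_fraction"] = _mito_fraction(out)
    return out, report


def lognormalize(adata: ad.AnnData, scale: float = 10_000.0) -> ad.AnnData:
    """Library-size log-normalization: log(1 + scale * count / libsize).

    Natural log.  Raw counts are kept in ``layers['counts']``.  Cells with
    zero total counts are an error (they should have been removed by QC).
    """
    X = np.asarray(adata.X, dtype=float)
    libsize = X.sum(axis=1)
    if (libsize == 0).any():
        raise ValueError("cell(s) with zero total counts; run qc_filter first")
    out = adata.copy()
    out.layers["counts"] = X.copy()
    out.X = np.log1p(scale * X / libsize[:, None])
    return out


def wilcoxon_de(adata: ad.AnnData, group_a: np.ndarray,
                group_b: np.ndarray) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum test between two disjoint cell groups.

    ``group_a`` / ``group_b`` are boolean masks or integer indices over
    ``adata`` (normalized expression expected in ``X``).  Returns a DataFrame
    indexed by gene with per-group means and detection fractions, the fold
    change (ratio of de-logged means with a small pseudocount), the U
    statistic for group A, the two-sided p-value, and the Benjamini-Hochberg
    adjusted p-value.

    When both groups have at most 10 cells and a gene has no cross-group
    ties, the exact permutation null of U is used; otherwise the normal
    approximation with tie-corrected variance and continuity correction.
    """
    a_idx = np.asarray(group_a)
    b_idx = np.asarray(group_b)
    if a_idx.dtype == bool:
        a_idx = np.where(a_idx)[0]
    if b_idx.dtype == bool:
        b_idx = np.where(b_idx)[0]
    if np.intersect1d(a_idx, b_idx).size:
        raise ValueError("groups overlap")
    if a_idx.size < 2 or b_idx.size < 2:
        raise ValueError("each group needs at least 2 cells")

    X = np.asarray(adata.X, dtype=float)
    A = X[a_idx]
    B = X[b_idx]
    n1, n2 = A.shape[0], B.shape[0]

    small = n1 <= 10 and n2 <= 10
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = scipy.stats.mannwhitneyu(
            A, B, axis=0, alternative="two-sided", method="asymptotic"
        )
    u = np.asarray(res.statistic, dtype=float)
    pval = np.asarray(res.pvalue, dtype=float)
    if small:
        # exact enumeration gene-by-gene where the data are tie-free
        for j in range(X.shape[1]):
            col = np.concatenate([A[:, j], B[:, j]])
            if np.unique(col).size == col.size:
                r = scipy.stats.mannwhitneyu(
                    A[:, j], B[:, j], alternative="two-sided", method="exact"
                )
                u[j] = r.statistic
                pval[j] = r.pvalue
    # constant genes: U = n1*n2/2, p = 1
    const = (X[np.concatenate([a_idx, b_idx])].std(axis=0) == 0)
    u[const] = n1 * n2 / 2.0
    pval[const] = 1.0
    pval = np.clip(pval, 0.0, 1.0)

    mean_a = A.mean(axis=0)
    mean_b = B.mean(axis=0)
    fc = (np.expm1(A).mean(axis=0) + _FC_EPS) / (np.expm1(B).mean(axis=0) + _FC_EPS)
    padj = multipletests(pval, method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "frac_a": (A > 0).mean(axis=0),
            "frac_b": (B > 0).mean(axis=0),
            "fold_change": fc,
            "u_stat": u,
            "pval": pval,
            "padj": padj,
        },
        index=adata.var_names,
    )


def de_filter(de: pd.DataFrame, min_fc: float = 1.2,
              max_adj_p: float = 0.01) -> list[str]:
    """Genes with fold change > ``min_fc`` and adjusted p < ``max_adj_p``.

    Sorted by descending fold change.  The thresholds default to the
    conventional single-cell marker cut-offs (FC > 1.2, adjusted P < 0.01).
    """
    hits = de[(de["fold_change"] > min_fc) & (de["padj"] < max_adj_p)]
    return hits.sort_values("fold_change", ascending=False).index.tolist()
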