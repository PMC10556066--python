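"""Gene-set enrichment scoring for cells and bulk samples.

Three scorers over a units x genes expression table:

* :func:`module_score` — per-cell set-mean expression minus the mean of
  expression-bin-matched control genes (the conventional single-cell module
  score with binned controls);
* :func:`ssgsea` — single-sample GSEA: per unit, the sum over the ranked
  gene list of the difference between the rank-weighted ECDF of in-set genes
  and the ECDF of out-of-set genes;
* :func:`zscore_enrichment` — the combined z method: per sample, the sum of
  set-gene z-scores divided by sqrt(set size).
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "GeneSetLibrary",
    "EnrichmentMatrix",
    "module_score",
    "ssgsea",
    "zscore_enrichment",
    "read_gmt",
    "write_gmt",
]

# Bundled gene sets: the 7-gene blast progenitor signature and the immune
# phenotype panels used for the risk-validation analysis.  "NFACT1" in the
# effector set is retained verbatim from the published panel even though it is
# presumably the NFATC1 symbol seen in the exhausted set; see default_library.
BLAST7 = ["CLEC11A", "PRAME", "AZU1", "NREP", "ARMH1", "C1QBP", "TRH"]
M1_MACROPHAGE = ["S100A8", "S100A9", "S100A12", "TYROBP", "VCAN", "CD68",
                 "MNDA", "CYBB", "STAT1"]
NAIVE_T = ["CCR7", "LEF1", "TCF7", "SELL"]
EFFECTOR_T = ["CCL5", "NKG7", "GNLY", "GZMA", "GZMK", "NFACT1"]
EXHAUSTED_T = ["HAVCR2", "LAG3", "PDCD1", "NFATC1", "TIGIT", "TOX"]
REGULATORY_T = ["CCL5", "KLRB1", "KLRD1", "GZMH", "CD69", "CD44"]


class GeneSetLibrary:
    """Named, ordered gene sets with GMT round-tripping."""

    def __init__(self, sets: dict[str, list[str]]):
        for name, genes in sets.items():
            if not genes:
                raise ValueError(f"gene set '{name}' is empty")
            if len(genes) != len(set(genes)):
                raise ValueError(f"gene set '{name}' has duplicate symbols")
        self.sets = dict(sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()

    @classmethod
    def default_library(cls) -> "GeneSetLibrary":
        """The bundled signature and immune phenotype sets.

        Note the effector-T set carries the symbol ``NFACT1`` as printed in
        its source panel; the exhausted-T set uses ``NFATC1``.  Both are kept
        verbatim rather than silently merged.
        """
        warnings.warn(
            "effectorT contains 'NFACT1' (as printed in its source panel); "
            "exhaustedT contains 'NFATC1'. Symbols are kept verbatim.",
            stacklevel=2,
        )
        return cls({
            "blast7": list(BLAST7),
            "M1": list(M1_MACROPHAGE),
            "naiveT": list(NAIVE_T),
            "effectorT": list(EFFECTOR_T),
            "exhaustedT": list(EXHAUSTED_T),
            "regulatoryT": list(REGULATORY_T),
        })

    def to_gmt(self, path: str | Path) -> None:
        write_gmt(self.sets, path)

    @classmethod
    def from_gmt(cls, path: str | Path) -> "GeneSetLibrary":
        return cls(read_gmt(path))


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    lines = ["\t".join([name, name] + list(genes)) for name, genes in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


@dataclasses.dataclass
class EnrichmentMatrix:
    """Units x gene-sets score table with the method that produced it."""

    scores: pd.DataFrame
    method: str
    params: dict = dataclasses.field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        self.scores.to_csv(path, sep="\t")


def _as_frame(m) -> pd.DataFrame:
    if isinstance(m, ad.AnnData):
        return pd.DataFrame(np.asarray(m.X, dtype=float), index=m.obs_names,
                            columns=m.var_names)
    return pd.DataFrame(m).astype(float)


def module_score(m: ad.AnnData | pd.DataFrame, genes: list[str],
                 n_bins: int = 24, n_ctrl: int = 100,
                 seed: int = 0) -> pd.Series:
    """Binned-control module score, per cell.

    Genes are binned into ``n_bins`` equal-frequency bins of average
    expression across cells.  For each set gene, ``n_ctrl`` control genes are
    sampled from its bin (excluding set genes; with replacement when the bin
    holds fewer than ``n_ctrl`` candidates).  The score is the mean set-gene
    expression minus the mean control-gene expression, per cell.
    Deterministic given ``seed``.  Set genes absent from the matrix are
    dropped with a warning; an empty intersection is an error.
    """
    expr = _as_frame(m)
    present = [g for g in genes if g in expr.columns]
    missing = sorted(set(genes) - set(present))
    if missing:
        warnings.warn(f"set gene(s) absent from matrix, dropped: "
                      f"{', '.join(missing)}")
    if not present:
        raise ValueError("no set gene present in the expression matrix")

    rng = np.random.default_rng(seed)
    gene_means = expr.mean(axis=0)
    # equal-frequency bins of average expression (ties broken by rank order)
    order_ranks = gene_means.rank(method="first")
    bins = pd.cut(order_ranks, bins=n_bins, labels=False)
    set_mask = expr.columns.isin(present)

    ctrl_genes: list[str] = []
    for g in present:
        b = bins[g]
        pool = expr.columns[(bins == b).to_numpy() & ~set_mask]
        if pool.empty:
            pool = expr.columns[~set_mask]
        replace = len(pool) < n_ctrl
        ctrl_genes.extend(rng.choice(pool, size=n_ctrl, replace=replace))

    score = expr[present].mean(axis=1) - expr[ctrl_genes].mean(axis=1)
    score.name = "module_score"
    return score


def _ssgsea_unit(values: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """ssGSEA running-sum total for one unit.

    Genes are ordered by decreasing expression; in-set genes contribute
    ``rank^alpha`` weights (ascending midranks, so the most highly expressed
    gene carries the largest weight and ties share one) to the weighted
    ECDF, out-of-set genes contribute uniformly to the plain ECDF; the score
    is the sum of the ECDF differences over all positions.
    """
    n = values.size
    # ascending midranks: highest expression -> rank n, so top-ranked genes
    # carry the largest ECDF weight
    asc_rank = scipy.stats.rankdata(values, method="average")
    order = np.argsort(-values, kind="stable")
    w = np.where(in_set[order], asc_rank[order] ** alpha, 0.0)
    p_in = np.cumsum(w)
    total_in = p_in[-1]
    if total_in == 0:
        return 0.0
    p_in = p_in / total_in
    out = (~in_set[order]).astype(float)
    p_out = np.cumsum(out) / out.sum()
    return float(np.sum(p_in - p_out))


def ssgsea(m: ad.AnnData | pd.DataFrame, sets: GeneSetLibrary | dict,
           alpha: float = 0.25, normalize: bool = False) -> EnrichmentMatrix:
    """Single-sample GSEA scores for every unit and gene set.

    ``alpha`` is the rank-weighting exponent.  With ``normalize=True``
    scores are divided by (max - min) across units, per set.  Sets with
    fewer than two genes present in the matrix are skipped with a warning.
    """
    expr = _as_frame(m)
    if isinstance(sets, dict):
        sets = GeneSetLibrary(sets)
    X = expr.to_numpy()
    cols = {}
    for name, genes in sets.items():
        in_set = expr.columns.isin(genes)
        if in_set.sum() < 2:
            warnings.warn(f"gene set '{name}' has <2 genes in the matrix; "
                          "column skipped")
            continue
        cols[name] = np.array(
            [_ssgsea_unit(X[i], in_set, alpha) for i in range(X.shape[0])]
        )
    scores = pd.DataFrame(cols, index=expr.index)
    if normalize and not scores.empty:
        rng_ = scores.max(axis=0) - scores.min(axis=0)
        rng_[rng_ == 0] = 1.0
        scores = scores / rng_
    return EnrichmentMatrix(scores=scores, method="ssgsea",
                            params={"alpha": alpha, "normalize": normalize})


def zscore_enrichment(m: ad.AnnData | pd.DataFrame,
                      genes: list[str]) -> pd.Series:
    """Combined z-score enrichment of a gene set, per sample.

    Each gene is z-scored across samples (ddof=1); a sample's combined score
    is the sum of its k set-gene z-scores divided by sqrt(k).  Genes with
    zero variance across samples are dropped with a warning; dropping all of
    them is an error.
    """
    expr = _as_frame(m)
    present = [g for g in genes if g in expr.columns]
    missing = sorted(set(genes) - set(present))
    if missing:
        warnings.warn(f"set gene(s) absent from matrix, dropped: "
                      f"{', '.join(missing)}")
    usable = []
    for g in present:
        if expr[g].std(ddof=1) == 0:
            warnings.warn(f"gene '{g}' has zero variance across samples; dropped")
        else:
            usable.append(g)
    if not usable:
        raise ValueError("no usable set gene (all absent or zero-variance)")
    sub = expr[usable]
    z = (sub - sub.mean(axis=0)) / sub.std(axis=0, ddof=1)
    combined = z.sum(axis=1) / np.sqrt(len(usable))
    combined.name = "zscore"
    return combined
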