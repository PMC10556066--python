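"""Leukemic-stem-cell (LSC6) risk scoring and immune-signature validation.

The LSC6 score is a weighted sum of six stemness genes (DNMT3B, GPR56, CD34,
SOCS2, SPINK2, FAM30A) whose published weights come from its original
derivation; they are therefore user-supplied, never bundled.  Samples are
binned into low / medium / high risk at the published boundaries (<0.95,
[0.95, 1.9), >=1.9), and immune gene-set enrichment (ssGSEA) is related to
risk by Pearson correlation and rank-based between-bin comparisons.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import scipy.stats

from . import scoring
from .syndata import BulkCohort

__all__ = ["LSC6_GENES", "Lsc6Model", "lsc6_score", "risk_bin",
           "enrichment_vs_risk"]

LSC6_GENES = ("DNMT3B", "GPR56", "CD34", "SOCS2", "SPINK2", "FAM30A")
RISK_ORDER = ("low", "medium", "high")


@dataclasses.dataclass
class Lsc6Model:
    """Six-gene LSC risk model: user-supplied coefficients, fixed bin edges."""

    coefficients: dict[str, float]
    bin_edges: tuple[float, float] = (0.95, 1.9)

    def __post_init__(self) -> None:
        if self.coefficients is None or not self.coefficients:
            raise ValueError(
                "LSC6 coefficients must be supplied (they come from the "
                "score's original derivation and are not bundled); provide a "
                "{gene: weight} mapping for all six genes"
            )
        missing = set(LSC6_GENES) - set(self.coefficients)
        if missing:
            raise ValueError(f"missing LSC6 coefficient(s): {sorted(missing)}")
        vals = [self.coefficients[g] for g in LSC6_GENES]
        if not np.isfinite(vals).all():
            raise ValueError("LSC6 coefficients must be finite")
        if not self.bin_edges[0] < self.bin_edges[1]:
            raise ValueError("bin edges must be strictly increasing")


def lsc6_score(cohort: BulkCohort | pd.DataFrame, model: Lsc6Model,
               log_transform: bool = True) -> pd.Series:
    """Per-sample LSC6 score: sum of coefficient * expression over six genes.

    Expression defaults to log2(x + 1) of the cohort table (the score is
    defined on log-scale expression); pass ``log_transform=False`` when the
    table is already on log scale.  A missing gene is an error naming it.
    """
    expr = cohort.expression if isinstance(cohort, BulkCohort) else cohort
    missing = [g for g in LSC6_GENES if g not in expr.columns]
    if missing:
        raise ValueError(f"LSC6 gene(s) missing from cohort: {', '.join(missing)}")
    x = expr[list(LSC6_GENES)].astype(float)
    if log_transform:
        x = np.log2(x + 1.0)
    coef = pd.Series({g: model.coefficients[g] for g in LSC6_GENES})
    score = x @ coef
    score.name = "lsc6"
    return score


def risk_bin(scores, model: Lsc6Model | None = None) -> pd.Series:
    """Categorize LSC6 scores: low < 0.95 <= medium < 1.9 <= high."""
    lo, hi = model.bin_edges if model is not None else (0.95, 1.9)
    s = pd.Series(scores, dtype=float)
    if not np.isfinite(s.to_numpy()).all():
        raise ValueError("scores must be finite")
    cats = np.where(s < lo, "low", np.where(s < hi, "medium", "high"))
    return pd.Series(pd.Categorical(cats, categories=list(RISK_ORDER)),
                     index=s.index, name="risk")


def enrichment_vs_risk(cohort: BulkCohort, sets: scoring.GeneSetLibrary,
                       lsc6: pd.Series, alpha: float = 0.25,
                       min_bin_n: int = 3,
                       log_transform: bool = True
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relate immune gene-set enrichment to LSC6 risk.

    Computes ssGSEA scores for every set on the cohort (log2(x+1) scale by
    default), then per set: the Pearson correlation (r, two-sided p) with the
    LSC6 score, and rank-sum (Mann-Whitney) p-values for every pair of risk
    bins.  Bins with fewer than ``min_bin_n`` samples are excluded from the
    pairwise comparisons with a warning (mirroring the exclusion of
    underpopulated risk groups in practice).

    Returns ``(correlations, pairwise)`` DataFrames.
    """
    expr = cohort.expression.astype(float)
    if log_transform:
        expr = np.log2(expr + 1.0)
    enrich = scoring.ssgsea(expr, sets, alpha=alpha).scores
    lsc6 = lsc6.loc[enrich.index]
    bins = risk_bin(lsc6)

    corr_rows = []
    for name in enrich.columns:
        r, p = scipy.stats.pearsonr(lsc6.to_numpy(), enrich[name].to_numpy())
        corr_rows.append({"set": name, "pearson_r": r, "p": p})
    correlations = pd.DataFrame(corr_rows).set_index("set")

    usable = []
    for b in RISK_ORDER:
        n_b = int((bins == b).sum())
        if n_b >= min_bin_n:
            usable.append(b)
        elif n_b > 0:
            warnings.warn(f"risk bin '{b}' has only {n_b} sample(s); "
                          "pairwise comparisons skipped")
    pair_rows = []
    for i, a in enumerate(usable):
        for b in usable[i + 1:]:
            ia = (bins == a).to_numpy()
            ib = (bins == b).to_numpy()
            for name in enrich.columns:
                stat = scipy.stats.mannwhitneyu(
                    enrich[name].to_numpy()[ia], enrich[name].to_numpy()[ib],
                    alternative="two-sided",
                )
                pair_rows.append({"set": name, "bin_a": a, "bin_b": b,
                                  "n_a": int(ia.sum()), "n_b": int(ib.sum()),
                                  "p": float(stat.pvalue)})
    pairwise = pd.DataFrame(
        pair_rows, columns=["set", "bin_a", "bin_b", "n_a", "n_b", "p"]
    )
    return correlations, pairwise
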