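"""The multi-stage blast-signature discovery funnel.

Stage 1 is the single-cell DE gene list (``sc_prep``).  Stage 2 filters it
on an external bulk cohort binned by clinical blast percentage, keeping genes
that are progressively downregulated from high-blast to low-blast and
post-induction samples.  Stage 3 removes genes with appreciable expression in
the normal marrow microenvironment (off-target filter).  Stage 4 ranks the
survivors with linear SVM recursive feature elimination under repeated
stratified cross-validation and picks the smallest panel whose out-of-fold
ROC AUC is within a tolerance of the best panel.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from . import sc_prep
from .syndata import BulkCohort

__all__ = [
    "DiscoveryConfig",
    "SignatureTrace",
    "bin_by_blast_pct",
    "log2_cpm",
    "progressive_filter",
    "offtarget_filter",
    "svm_rfe",
    "roc_auc",
    "discover_signature",
]


@dataclasses.dataclass
class DiscoveryConfig:
    """Thresholds and settings of the discovery funnel.

    The single-cell and bulk filter thresholds default to the published
    funnel cut-offs: FC > 1.2 with adjusted P < 0.01 at the single-cell
    stage; FC > 1.8 with P < 0.03 (high-blast vs EOI) and P < 0.04
    (high-blast vs low-blast) at the bulk stage; candidate panels of 5-15
    genes for the SVM.
    """

    sc_min_fc: float = 1.2
    sc_max_adj_p: float = 0.01
    bulk_min_fc: float = 1.8
    p_high_vs_eoi: float = 0.03
    p_high_vs_low: float = 0.04
    offtarget_max_fraction: float = 0.10
    offtarget_max_ratio: float = 0.25
    panel_min: int = 5
    panel_max: int = 15
    cv_folds: int = 5
    cv_repeats: int = 10
    svm_C: float = 1.0
    auc_tolerance: float = 0.005
    high_bin_inclusive: bool = False  # ">60%" strict by default
    seed: int = 17

    def __post_init__(self) -> None:
        if self.panel_min > self.panel_max:
            raise ValueError("panel_min must not exceed panel_max")
        for name in ("sc_min_fc", "bulk_min_fc", "p_high_vs_eoi",
                     "p_high_vs_low", "offtarget_max_fraction",
                     "offtarget_max_ratio", "svm_C"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclasses.dataclass
class SignatureTrace:
    """Stage-wise record of the discovery funnel."""

    stage1_sc_de: list[str] = dataclasses.field(default_factory=list)
    stage2_bulk: list[str] = dataclasses.field(default_factory=list)
    stage3_offtarget: list[str] = dataclasses.field(default_factory=list)
    panel_rankings: dict[str, float] = dataclasses.field(default_factory=dict)
    cv_auc_by_size: dict[int, float] = dataclasses.field(default_factory=dict)
    final_panel: list[str] = dataclasses.field(default_factory=list)

    def validate_nesting(self) -> None:
        if not set(self.stage2_bulk) <= set(self.stage1_sc_de):
            raise ValueError("stage2 not a subset of stage1")
        if not set(self.stage3_offtarget) <= set(self.stage2_bulk):
            raise ValueError("stage3 not a subset of stage2")
        if not set(self.final_panel) <= set(self.stage3_offtarget):
            raise ValueError("final panel not a subset of stage3")

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["cv_auc_by_size"] = {str(k): v for k, v
                                     in self.cv_auc_by_size.items()}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureTrace":
        payload = json.loads(Path(path).read_text())
        payload["cv_auc_by_size"] = {int(k): v for k, v
                                     in payload["cv_auc_by_size"].items()}
        return cls(**payload)


def bin_by_blast_pct(cohort: BulkCohort,
                     high_bin_inclusive: bool = False) -> dict[str, np.ndarray]:
    """Partition samples into blast-percentage bins.

    Diagnosis samples go to ``high`` (>60% blasts), ``mid`` ([30, 60]%) or
    ``low`` (<30%); every EOI sample goes to ``eoi`` regardless of blast
    percentage.  Returns a dict of positional index arrays.  The 60% boundary
    is exclusive for the high bin by default (``blast_pct == 60`` is mid);
    set ``high_bin_inclusive`` to move it.
    """
    tp = cohort.meta["timepoint"].to_numpy()
    pct = cohort.meta["blast_pct"].to_numpy(dtype=float)
    is_dx = tp == "Dx"
    if np.isnan(pct[is_dx]).any():
        raise ValueError("Dx samples with missing blast_pct cannot be binned")
    if high_bin_inclusive:
        high = is_dx & (pct >= 60.0)
        mid = is_dx & (pct >= 30.0) & (pct < 60.0)
    else:
        high = is_dx & (pct > 60.0)
        mid = is_dx & (pct >= 30.0) & (pct <= 60.0)
    low = is_dx & (pct < 30.0)
    eoi = tp == "EOI"
    bins = {k: np.where(v)[0] for k, v in
            [("high", high), ("mid", mid), ("low", low), ("eoi", eoi)]}
    if bins["high"].size == 0:
        raise ValueError("empty high-blast bin: progressive filter undefined")
    if bins["eoi"].size == 0:
        raise ValueError("empty EOI bin: progressive filter undefined")
    return bins


def log2_cpm(expression: pd.DataFrame) -> pd.DataFrame:
    """log2(CPM + 1) normalization of a samples x genes count table."""
    lib = expression.sum(axis=1).to_numpy(dtype=float)
    if (lib == 0).any():
        raise ValueError("sample(s) with zero total counts")
    cpm = 1e6 * expression.to_numpy(dtype=float) / lib[:, None]
    return pd.DataFrame(np.log2(cpm + 1.0), index=expression.index,
                        columns=expression.columns)


def progressive_filter(cohort: BulkCohort, candidate_genes: list[str],
                       cfg: DiscoveryConfig,
                       bins: dict[str, np.ndarray] | None = None) -> list[str]:
    """Keep genes progressively downregulated from high-blast to EOI/low bins.

    A gene survives when its high-bin/EOI fold change exceeds
    ``cfg.bulk_min_fc`` with Welch t-test p < ``cfg.p_high_vs_eoi`` AND its
    high-bin/low-bin fold change exceeds ``cfg.bulk_min_fc`` with p <
    ``cfg.p_high_vs_low``.  Fold changes are ratios of linear-scale CPM
    means; t-tests run on log2(CPM+1).  Output sorted by descending high-bin
    mean expression.  Candidates missing from the cohort are skipped with a
    warning.
    """
    if bins is None:
        bins = bin_by_blast_pct(cohort, cfg.high_bin_inclusive)
    candidate_genes = list(dict.fromkeys(candidate_genes))
    present = [g for g in candidate_genes if g in cohort.expression.columns]
    missing = sorted(set(candidate_genes) - set(present))
    if missing:
        warnings.warn(f"{len(missing)} candidate gene(s) absent from cohort, "
                      f"skipped: {', '.join(missing[:5])}...")
    if not present:
        return []

    logx = log2_cpm(cohort.expression)[present]
    linx = np.exp2(logx) - 1.0

    kept = []
    high_means = {}
    for g in present:
        lg = logx[g].to_numpy()
        ln = linx[g].to_numpy()
        fc_eoi = (ln[bins["high"]].mean() + 1e-9) / (ln[bins["eoi"]].mean() + 1e-9)
        fc_low = np.inf
        if bins["low"].size >= 2:
            fc_low = (ln[bins["high"]].mean() + 1e-9) / (ln[bins["low"]].mean() + 1e-9)
        p_eoi = scipy.stats.ttest_ind(lg[bins["high"]], lg[bins["eoi"]],
                                      equal_var=False).pvalue
        p_low = (scipy.stats.ttest_ind(lg[bins["high"]], lg[bins["low"]],
                                       equal_var=False).pvalue
                 if bins["low"].size >= 2 else 0.0)
        if (fc_eoi > cfg.bulk_min_fc and p_eoi < cfg.p_high_vs_eoi
                and fc_low > cfg.bulk_min_fc and p_low < cfg.p_high_vs_low):
            kept.append(g)
            high_means[g] = lg[bins["high"]].mean()
    return sorted(kept, key=lambda g: -high_means[g])


def offtarget_filter(adata_norm: ad.AnnData, candidate_genes: list[str],
                     cfg: DiscoveryConfig,
                     label_col: str = "label") -> list[str]:
    """Drop genes appreciably expressed in the normal marrow microenvironment.

    A candidate is removed when the fraction of non-blast cells expressing it
    exceeds ``cfg.offtarget_max_fraction`` OR its non-blast/blast mean ratio
    (de-logged normalized scale) exceeds ``cfg.offtarget_max_ratio``.
    Preserves the input gene order.
    """
    labels = adata_norm.obs[label_col].to_numpy()
    nb = labels == "non-blast"
    bl = labels == "blast"
    if not nb.any():
        raise ValueError("no non-blast cells available for off-target filter")
    if not bl.any():
        raise ValueError("no blast cells available for off-target filter")

    present = [g for g in dict.fromkeys(candidate_genes)
               if g in adata_norm.var_names]
    missing = sorted(set(candidate_genes) - set(present))
    if missing:
        warnings.warn(f"{len(missing)} candidate gene(s) absent from matrix, "
                      f"skipped: {', '.join(missing[:5])}")
    X = np.asarray(adata_norm[:, present].X, dtype=float)
    lin = np.expm1(X)
    frac_nb = (X[nb] > 0).mean(axis=0)
    ratio = (lin[nb].mean(axis=0) + 1e-9) / (lin[bl].mean(axis=0) + 1e-9)
    keep = (frac_nb <= cfg.offtarget_max_fraction) & (ratio <= cfg.offtarget_max_ratio)
    return [g for g, k in zip(present, keep) if k]


def roc_auc(scores: np.ndarray, labels: np.ndarray,
            ci: bool = False, n_boot: int = 2000,
            seed: int = 0) -> float | tuple[float, tuple[float, float]]:
    """Area under the ROC curve by the rank (Mann-Whitney) formula.

    AUC = P(score_pos > score_neg) + 0.5 P(tie).  ``labels`` is binary
    (1 = positive).  With ``ci=True`` also returns a stratified percentile
    bootstrap 95% CI over ``n_boot`` resamples.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = scipy.stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    if not ci:
        return auc
    rng = np.random.default_rng(seed)
    pos = s[y == 1]
    neg = s[y == 0]
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bp = rng.choice(pos, size=n_pos, replace=True)
        bn = rng.choice(neg, size=n_neg, replace=True)
        br = scipy.stats.rankdata(np.concatenate([bp, bn]))
        boots[i] = (br[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return auc, (float(lo), float(hi))


def _fold_rfe_ranking(Xtr: np.ndarray, ytr: np.ndarray, cfg: DiscoveryConfig,
                      random_state: int) -> np.ndarray:
    """SVM-RFE feature ranking on one training fold.

    Returns ranks 1..n_features (1 = most important): features eliminated
    earlier rank worse; the ``panel_min`` survivors are ordered by final
    absolute weight.
    """
    n_feat = Xtr.shape[1]
    active = list(range(n_feat))
    eliminated: list[int] = []
    weights_final = None
    while True:
        clf = LinearSVC(C=cfg.svm_C, dual=False, max_iter=5000,
                        random_state=random_state)
        clf.fit(Xtr[:, active], ytr)
        w = np.abs(clf.coef_.ravel())
        if len(active) <= cfg.panel_min:
            weights_final = w
            break
        drop = int(np.argmin(w))
        eliminated.append(active.pop(drop))
    ranks = np.empty(n_feat, dtype=float)
    surv_order = np.argsort(-weights_final, kind="stable")
    for r, j in enumerate(surv_order):
        ranks[active[j]] = r + 1
    for r, feat in enumerate(reversed(eliminated)):
        ranks[feat] = len(active) + r + 1
    return ranks


def svm_rfe(X: np.ndarray | pd.DataFrame, y: np.ndarray,
            cfg: DiscoveryConfig,
            gene_names: list[str] | None = None) -> SignatureTrace:
    """Rank candidate genes by linear SVM-RFE and choose a minimal panel.

    Features are z-standardized per training fold.  Within each fold of a
    repeated stratified k-fold scheme, a linear SVM is fit and the feature
    with the smallest absolute weight is iteratively removed down to
    ``cfg.panel_min`` features; per-fold ranks are averaged into the
    aggregate ranking.  For every panel size in
    [``panel_min``, ``panel_max``] the out-of-fold ROC AUC of an SVM trained
    on each fold's own top genes is computed; the final panel is the smallest
    size whose mean AUC is within ``cfg.auc_tolerance`` of the best.
    Deterministic given ``cfg.seed``.
    """
    if isinstance(X, pd.DataFrame):
        gene_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if gene_names is None:
            gene_names = [f"f{i}" for i in range(X.shape[1])]
    y = np.asarray(y)
    if y.dtype.kind in "UOS":
        y = (y == "blast").astype(int)
    y = y.astype(int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be present in y")
    n_feat = X.shape[1]
    if n_feat < cfg.panel_min:
        raise ValueError(
            f"{n_feat} candidate genes < minimum panel size {cfg.panel_min}"
        )
    sizes = list(range(cfg.panel_min, min(cfg.panel_max, n_feat) + 1))

    rank_sum = np.zeros(n_feat)
    n_folds_total = 0
    oof_scores: dict[int, list[tuple[np.ndarray, np.ndarray]]] = {
        s: [] for s in sizes
    }
    for rep in range(cfg.cv_repeats):
        skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True,
                              random_state=cfg.seed + 1000 * rep)
        for tr, te in skf.split(X, y):
            mu = X[tr].mean(axis=0)
            sd = X[tr].std(axis=0)
            sd[sd == 0] = 1.0
            Xtr = (X[tr] - mu) / sd
            Xte = (X[te] - mu) / sd
            ranks = _fold_rfe_ranking(Xtr, y[tr], cfg, random_state=cfg.seed)
            rank_sum += ranks
            n_folds_total += 1
            order = np.argsort(ranks, kind="stable")
            for s in sizes:
                top = order[:s]
                clf = LinearSVC(C=cfg.svm_C, dual=False, max_iter=5000,
                                random_state=cfg.seed)
                clf.fit(Xtr[:, top], y[tr])
                oof_scores[s].append(
                    (clf.decision_function(Xte[:, top]), y[te])
                )

    mean_rank = rank_sum / n_folds_total
    agg_order = sorted(range(n_feat), key=lambda j: (mean_rank[j], gene_names[j]))

    auc_by_size: dict[int, float] = {}
    per_rep = cfg.cv_folds
    for s in sizes:
        chunks = oof_scores[s]
        rep_aucs = []
        for r in range(cfg.cv_repeats):
            block = chunks[r * per_rep:(r + 1) * per_rep]
            sc = np.concatenate([b[0] for b in block])
            yy = np.concatenate([b[1] for b in block])
            rep_aucs.append(roc_auc(sc, yy))
        auc_by_size[s] = float(np.mean(rep_aucs))

    best = max(auc_by_size.values())
    final_size = min(s for s in sizes if auc_by_size[s] >= best - cfg.auc_tolerance)
    final_panel = [gene_names[j] for j in agg_order[:final_size]]

    return SignatureTrace(
        panel_rankings={gene_names[j]: float(mean_rank[j]) for j in range(n_feat)},
        cv_auc_by_size=auc_by_size,
        final_panel=final_panel,
    )


def discover_signature(adata: ad.AnnData, cohort: BulkCohort,
                       cfg: DiscoveryConfig | None = None,
                       qc: bool = True) -> SignatureTrace:
    """Run the full funnel: QC -> DE -> bulk filter -> off-target -> SVM-RFE.

    ``adata`` carries raw counts with blast / non-blast labels in
    ``obs['label']``; ``cohort`` is the external bulk cohort with blast
    percentages and timepoints.  Returns the complete
    :class:`SignatureTrace`.
    """
    cfg = cfg or DiscoveryConfig()
    if qc:
        adata, _ = sc_prep.qc_filter(adata)
    norm = sc_prep.lognormalize(adata)
    labels = norm.obs["label"].to_numpy()
    de = sc_prep.wilcoxon_de(norm, labels == "blast", labels == "non-blast")
    stage1 = sc_prep.de_filter(de, cfg.sc_min_fc, cfg.sc_max_adj_p)
    stage2 = progressive_filter(cohort, stage1, cfg)
    stage3 = offtarget_filter(norm, stage2, cfg)
    if len(stage3) < cfg.panel_min:
        raise ValueError(
            f"only {len(stage3)} genes survive the funnel; "
            f"cannot build a panel of at least {cfg.panel_min}"
        )
    Xc = pd.DataFrame(np.asarray(norm[:, stage3].X), columns=stage3)
    trace = svm_rfe(Xc, labels, cfg)
    trace.stage1_sc_de = stage1
    trace.stage2_bulk = stage2
    trace.stage3_offtarget = stage3
    trace.validate_nesting()
    return trace
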