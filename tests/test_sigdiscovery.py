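"""Funnel stages, SVM-RFE ranking, and ROC AUC against independent oracles."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from blastsig.sigdiscovery import (
    DiscoveryConfig,
    bin_by_blast_pct,
    discover_signature,
    log2_cpm,
    offtarget_filter,
    progressive_filter,
    roc_auc,
    svm_rfe,
)
from blastsig.syndata import BulkCohort, expression_profiles, generate_bulk_cohort, generate_single_cell


def _cohort_from(pcts, timepoints, expr=None, genes=3):
    n = len(pcts)
    idx = pd.Index([f"S{i}" for i in range(n)], name="sample_id")
    if expr is None:
        expr = np.ones((n, genes))
    expression = pd.DataFrame(expr, index=idx,
                              columns=[f"G{j}" for j in range(expr.shape[1])])
    meta = pd.DataFrame({"blast_pct": pcts, "timepoint": timepoints}, index=idx)
    return BulkCohort(expression=expression, meta=meta)


class TestBins:
    def test_hand_partition(self):
        pcts = [80, 61, 60.0, 45, 30, 29.9, 5, 95, np.nan, np.nan]
        tps = ["Dx"] * 8 + ["EOI", "EOI"]
        bins = bin_by_blast_pct(_cohort_from(pcts, tps))
        assert list(bins["high"]) == [0, 1, 7]   # >60 strictly
        assert list(bins["mid"]) == [2, 3, 4]    # [30, 60] closed
        assert list(bins["low"]) == [5, 6]       # <30 strictly
        assert list(bins["eoi"]) == [8, 9]
        # every Dx sample in exactly one bin
        dx_union = sorted(np.concatenate([bins["high"], bins["mid"], bins["low"]]))
        assert dx_union == list(range(8))

    def test_boundary_60_is_mid(self):
        bins = bin_by_blast_pct(_cohort_from([60.0, 61.0, 70.0], ["Dx"] * 2 + ["EOI"]))
        assert 0 in bins["mid"] and 1 in bins["high"]

    def test_empty_high_bin_raises(self):
        with pytest.raises(ValueError, match="high"):
            bin_by_blast_pct(_cohort_from([10, 20, 5], ["Dx", "Dx", "EOI"]))


class TestProgressiveFilter:
    def _bins_cohort(self, rng, gene_cols):
        n_per = 20
        pcts = [80.0] * n_per + [45.0] * n_per + [10.0] * n_per + [np.nan] * n_per
        tps = ["Dx"] * (3 * n_per) + ["EOI"] * n_per
        expr = np.column_stack(gene_cols)
        return _cohort_from(pcts, tps, expr)

    def test_constant_gene_excluded_strong_gene_retained(self, rng):
        n = 80
        base = rng.poisson(1000.0, size=n).astype(float)
        strong = np.where(np.arange(n) < 20, 10_000.0, 0.0) + rng.poisson(100.0, n)
        strong[20:] = rng.poisson(100.0, 60)  # high bin 100x others
        strong[:20] = rng.poisson(10_000.0, 20)
        cohort = self._bins_cohort(rng, [base, strong])
        kept = progressive_filter(cohort, ["G0", "G1"], DiscoveryConfig())
        assert kept == ["G1"]

    def test_planted_recovery_with_low_false_positive_rate(self, small_config):
        cfg = dataclasses.replace(small_config, n_bulk_samples=124, n_bulk_eoi=24)
        prof = expression_profiles(cfg)
        cohort = generate_bulk_cohort(cfg, prof["blast"], prof["normal"])
        genes = list(cohort.expression.columns)
        kept = progressive_filter(cohort, genes, DiscoveryConfig())
        strong = [g for g, f in zip(cfg.planted_genes, cfg.planted_log2fc)
                  if f >= 2.0]
        assert set(strong) <= set(kept)
        null_kept = set(kept) - set(cfg.planted_genes)
        assert len(null_kept) <= 0.05 * (cfg.n_genes - 7)

    def test_missing_gene_warns(self, small_cohort):
        with pytest.warns(UserWarning, match="absent"):
            progressive_filter(small_cohort, ["NOT_A_GENE", "CLEC11A"],
                               DiscoveryConfig())

    def test_oracle_direct_t_tests(self, small_cohort):
        """Survivors match a direct recomputation of both FC/t rules."""
        cfg = DiscoveryConfig()
        genes = list(small_cohort.expression.columns[:50]) + ["CLEC11A"]
        kept = progressive_filter(small_cohort, genes, cfg)
        bins = bin_by_blast_pct(small_cohort)
        logx = log2_cpm(small_cohort.expression)
        expect = []
        for g in genes:
            lin = np.exp2(logx[g].to_numpy()) - 1
            lg = logx[g].to_numpy()
            ok = True
            for other, pmax in (("eoi", cfg.p_high_vs_eoi), ("low", cfg.p_high_vs_low)):
                fc = (lin[bins["high"]].mean() + 1e-9) / (lin[bins[other]].mean() + 1e-9)
                p = scipy.stats.ttest_ind(lg[bins["high"]], lg[bins[other]],
                                          equal_var=False).pvalue
                ok &= (fc > cfg.bulk_min_fc) and (p < pmax)
            if ok:
                expect.append(g)
        assert set(kept) == set(expect)


class TestOfftargetFilter:
    def _adata(self, X, labels):
        import anndata as ad
        n, g = X.shape
        a = ad.AnnData(X=X.astype(float),
                       obs=pd.DataFrame({"label": labels},
                                        index=[f"c{i}" for i in range(n)]),
                       var=pd.DataFrame(index=[f"G{j}" for j in range(g)]))
        return a

    def test_constructed_fractions_match_hand_computed_set(self, rng):
        n_nb, n_bl = 50, 50
        X = np.zeros((100, 20))
        cfg = DiscoveryConfig()
        keep_expect = []
        for j in range(20):
            frac = j / 20.0                 # non-blast detection fraction
            k = int(frac * n_nb)
            X[:k, j] = 1.0                  # non-blast cells first
            X[n_nb:, j] = 5.0               # blast cells expression
            ratio = (k * np.expm1(1.0) / n_nb) / np.expm1(5.0)
            if frac <= cfg.offtarget_max_fraction and ratio <= cfg.offtarget_max_ratio:
                keep_expect.append(f"G{j}")
        labels = ["non-blast"] * n_nb + ["blast"] * n_bl
        kept = offtarget_filter(self._adata(X, labels),
                                [f"G{j}" for j in range(20)], cfg)
        assert kept == keep_expect

    def test_silent_in_nonblast_retained_equal_means_removed(self):
        X = np.zeros((40, 2))
        X[20:, 0] = 3.0                     # gene 0: blast-only
        X[:, 1] = 2.0                       # gene 1: equal everywhere
        labels = ["non-blast"] * 20 + ["blast"] * 20
        kept = offtarget_filter(self._adata(X, labels), ["G0", "G1"],
                                DiscoveryConfig())
        assert kept == ["G0"]

    def test_no_nonblast_cells_raises(self):
        X = np.ones((10, 3))
        with pytest.raises(ValueError, match="non-blast"):
            offtarget_filter(self._adata(X, ["blast"] * 10), ["G0"],
                             DiscoveryConfig())


class TestRocAuc:
    def test_perfect_and_degenerate(self):
        assert roc_auc(np.array([1, 2, 3, 4.0]), np.array([0, 0, 1, 1])) == 1.0
        assert roc_auc(np.ones(10), np.r_[np.ones(5), np.zeros(5)]) == 0.5

    def test_matches_pairwise_concordance_oracle(self, rng):
        scores = rng.normal(size=12)
        scores[3] = scores[9]               # inject a tie
        y = np.r_[np.ones(6), np.zeros(6)].astype(int)
        pos, neg = scores[y == 1], scores[y == 0]
        conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert roc_auc(scores, y) == pytest.approx(conc / 36.0, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=40)
        y = (rng.uniform(size=40) > 0.5).astype(int)
        a1 = roc_auc(scores, y)
        a2 = roc_auc(np.exp(scores), y)
        assert a1 == pytest.approx(a2, abs=1e-15)

    def test_ci_brackets_point_estimate(self, rng):
        scores = rng.normal(size=60) + np.r_[np.ones(30), np.zeros(30)]
        y = np.r_[np.ones(30), np.zeros(30)].astype(int)
        auc, (lo, hi) = roc_auc(scores, y, ci=True, n_boot=200, seed=1)
        assert lo <= auc <= hi

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="class"):
            roc_auc(np.arange(4.0), np.ones(4))


class TestSvmRfe:
    def test_separating_feature_ranked_first(self, rng):
        n = 120
        X = rng.normal(size=(n, 20))
        y = (rng.uniform(size=n) > 0.5).astype(int)
        X[:, 7] = y * 4.0 + rng.normal(scale=0.05, size=n)
        cfg = DiscoveryConfig(cv_repeats=2, seed=1)
        trace = svm_rfe(X, y, cfg)
        ranked = sorted(trace.panel_rankings, key=trace.panel_rankings.get)
        assert ranked[0] == "f7"
        assert trace.cv_auc_by_size[5] == pytest.approx(1.0, abs=1e-9)

    def test_permuted_labels_give_chance_auc(self, rng):
        n = 200
        X = rng.normal(size=(n, 12))
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
        y = rng.permutation(y)
        cfg = DiscoveryConfig(cv_repeats=3, seed=2)
        trace = svm_rfe(X, y, cfg)
        mean_auc = np.mean(list(trace.cv_auc_by_size.values()))
        assert 0.4 <= mean_auc <= 0.6

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(80, 8))
        y = (X[:, 0] + rng.normal(scale=1.0, size=80) > 0).astype(int)
        cfg = DiscoveryConfig(cv_repeats=2, seed=5)
        t1 = svm_rfe(X.copy(), y.copy(), cfg)
        t2 = svm_rfe(X.copy(), y.copy(), cfg)
        assert t1.panel_rankings == t2.panel_rankings
        assert t1.cv_auc_by_size == t2.cv_auc_by_size
        assert t1.final_panel == t2.final_panel

    def test_errors(self, rng):
        X = rng.normal(size=(20, 8))
        with pytest.raises(ValueError, match="class"):
            svm_rfe(X, np.ones(20), DiscoveryConfig())
        with pytest.raises(ValueError, match="panel"):
            svm_rfe(X[:, :3], (X[:, 0] > 0).astype(int), DiscoveryConfig())


def test_end_to_end_funnel_nesting_and_recovery(small_config):
    cfg = dataclasses.replace(small_config, n_bulk_samples=124, n_bulk_eoi=24,
                              n_blast_cells=400, n_nonblast_cells=400)
    adata = generate_single_cell(cfg)
    prof = expression_profiles(cfg)
    cohort = generate_bulk_cohort(cfg, prof["blast"], prof["normal"])
    dcfg = DiscoveryConfig(cv_repeats=2, seed=1)
    trace = discover_signature(adata, cohort, dcfg)
    trace.validate_nesting()
    assert set(trace.stage2_bulk) <= set(trace.stage1_sc_de)
    assert set(trace.stage3_offtarget) <= set(trace.stage2_bulk)
    assert set(trace.final_panel) <= set(trace.stage3_offtarget)
    strong = {g for g, f in zip(cfg.planted_genes, cfg.planted_log2fc) if f >= 2.8}
    assert len(strong & set(trace.final_panel)) >= 5


def test_trace_json_roundtrip(tmp_path):
    from blastsig.sigdiscovery import SignatureTrace
    tr = SignatureTrace(stage1_sc_de=["A", "B"], stage2_bulk=["A"],
                        stage3_offtarget=["A"], panel_rankings={"A": 1.0},
                        cv_auc_by_size={5: 0.9}, final_panel=["A"])
    tr.to_json(tmp_path / "t.json")
    back = SignatureTrace.from_json(tmp_path / "t.json")
    assert back == tr
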