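"""QC, normalization and Wilcoxon DE against exhaustive / enumeration oracles."""

import itertools

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from blastsig.sc_prep import de_filter, lognormalize, qc_filter, wilcoxon_de
from blastsig.syndata import SimConfig, generate_single_cell


def _toy_adata(counts: np.ndarray, gene_prefix: str = "G") -> ad.AnnData:
    n, g = counts.shape
    var = pd.DataFrame(index=[f"{gene_prefix}{j}" for j in range(g)])
    var["mt"] = False
    return ad.AnnData(X=counts.astype(float), var=var,
                      obs=pd.DataFrame(index=[f"c{i}" for i in range(n)]))


class TestQcFilter:
    def test_constructed_case_matches_brute_force(self, rng):
        # 10 cells x 40 genes; cell 0 is pure-mito, cells 1-2 detect too few
        # genes, gene 0 is expressed in too few surviving cells
        counts = rng.poisson(2.0, size=(10, 40))
        counts[:, 0] = 0
        counts[[3, 7], 0] = 1            # gene 0: detected in 2 cells only
        counts[0] = 0
        counts[0, 39] = 50               # MT gene below
        counts[1, :] = 0
        counts[1, 5:10] = 1              # 5 detected genes
        counts[2, :] = 0
        counts[2, 5:15] = 1              # 10 detected genes
        adata = _toy_adata(counts)
        adata.var["mt"] = [False] * 39 + [True]

        out, report = qc_filter(adata, max_mito=0.25, min_genes_per_cell=20,
                                min_cells_per_gene=3)

        # brute-force oracle
        mito_frac = counts[:, 39:].sum(1) / counts.sum(1)
        keep_cells = [i for i in range(10)
                      if mito_frac[i] <= 0.25 and (counts[i] > 0).sum() >= 20]
        keep_genes = [j for j in range(40)
                      if sum(counts[i, j] > 0 for i in keep_cells) >= 3]
        assert out.n_obs == len(keep_cells) == 7
        assert out.n_vars == len(keep_genes)
        assert np.array_equal(np.asarray(out.X),
                              counts[np.ix_(keep_cells, keep_genes)])
        assert report.n_cells_removed_mito == 1
        assert report.n_cells_removed_genes == 2

    def test_pure_mito_cell_removed(self, rng):
        counts = rng.poisson(3.0, size=(5, 10)) + 1
        counts[4, :] = 0
        counts[4, 9] = 10
        adata = _toy_adata(counts)
        adata.var["mt"] = [False] * 9 + [True]
        out, _ = qc_filter(adata, max_mito=0.25, min_genes_per_cell=0,
                           min_cells_per_gene=0)
        assert "c4" not in out.obs_names

    def test_identity_thresholds(self, small_cells):
        out, report = qc_filter(small_cells, max_mito=1.0,
                                min_genes_per_cell=0, min_cells_per_gene=0)
        assert out.shape == small_cells.shape
        assert report.n_genes_removed == 0

    def test_idempotent(self, small_cells):
        once, _ = qc_filter(small_cells)
        twice, rep = qc_filter(once)
        assert twice.shape == once.shape
        assert rep.n_cells_removed_mito == rep.n_cells_removed_genes == 0

    def test_all_cells_removed_raises(self, rng):
        counts = np.ones((3, 5))
        adata = _toy_adata(counts)
        with pytest.raises(ValueError, match="all cells removed"):
            qc_filter(adata, max_mito=1.0, min_genes_per_cell=10,
                      min_cells_per_gene=0)


class TestLognormalize:
    def test_matches_double_loop(self, rng):
        counts = rng.poisson(4.0, size=(5, 4)) + 1
        out = lognormalize(_toy_adata(counts), scale=1000.0)
        expect = np.empty((5, 4))
        for i in range(5):
            lib = counts[i].sum()
            for j in range(4):
                expect[i, j] = np.log(1 + 1000.0 * counts[i, j] / lib)
        assert np.allclose(np.asarray(out.X), expect, atol=1e-12)

    def test_symmetric_two_gene_cell(self):
        out = lognormalize(_toy_adata(np.array([[5, 5]])), scale=10.0)
        assert np.allclose(np.asarray(out.X), np.log(6.0))

    def test_zero_gene_stays_zero(self, rng):
        counts = rng.poisson(4.0, size=(4, 3)) + 1
        counts[:, 1] = 0
        out = lognormalize(_toy_adata(counts))
        assert (np.asarray(out.X)[:, 1] == 0).all()

    def test_zero_count_cell_raises(self):
        counts = np.array([[1, 2], [0, 0]])
        with pytest.raises(ValueError, match="zero total counts"):
            lognormalize(_toy_adata(counts))


class TestWilcoxonDE:
    def test_identical_group_distributions(self, rng):
        vals = rng.normal(size=8)
        counts = np.concatenate([vals, rng.permutation(vals)])[:, None]
        adata = _toy_adata(counts)
        de = wilcoxon_de(adata, np.arange(8), np.arange(8, 16))
        assert de["u_stat"].iloc[0] == pytest.approx(32.0)  # |A||B|/2
        assert de["pval"].iloc[0] > 0.9

    def test_exact_mode_matches_full_enumeration(self, rng):
        a = np.array([0.3, 2.1, 3.7, 5.2])
        b = np.array([1.1, 1.9, 4.4, 6.3])
        adata = _toy_adata(np.concatenate([a, b])[:, None])
        de = wilcoxon_de(adata, np.arange(4), np.arange(4, 8))

        # oracle: enumerate all C(8,4) assignments of the pooled values
        pooled = np.concatenate([a, b])
        ranks = pooled.argsort().argsort() + 1
        u_obs = de["u_stat"].iloc[0]
        mu = 4 * 4 / 2.0
        null_u = []
        for comb in itertools.combinations(range(8), 4):
            u = ranks[list(comb)].sum() - 4 * 5 / 2.0
            null_u.append(u)
        null_u = np.array(null_u)
        p_oracle = np.mean(np.abs(null_u - mu) >= abs(u_obs - mu))
        assert de["pval"].iloc[0] == pytest.approx(p_oracle, abs=1e-12)

    def test_rank_invariance_under_monotone_transform(self, rng):
        counts = rng.poisson(3.0, size=(30, 5)).astype(float)
        adata = _toy_adata(counts)
        a, b = np.arange(15), np.arange(15, 30)
        de1 = wilcoxon_de(adata, a, b)
        transformed = _toy_adata(np.exp(counts / 2.0))
        de2 = wilcoxon_de(transformed, a, b)
        assert np.allclose(de1["u_stat"], de2["u_stat"])
        assert np.allclose(de1["pval"], de2["pval"])

    def test_overlapping_groups_raise(self, rng):
        adata = _toy_adata(rng.poisson(2.0, size=(10, 3)))
        with pytest.raises(ValueError, match="overlap"):
            wilcoxon_de(adata, np.arange(5), np.arange(4, 10))

    def test_type_one_error_calibration(self, rng):
        """Null NB data: the raw p<0.01 rate stays near nominal."""
        counts = rng.negative_binomial(5, 5 / 7.0, size=(200, 2000))
        adata = _toy_adata(counts)
        de = wilcoxon_de(adata, np.arange(100), np.arange(100, 200))
        frac = (de["pval"] < 0.01).mean()
        assert 0.005 <= frac <= 0.02


class TestBenjaminiHochberg:
    @staticmethod
    def _bh_brute_force(p: np.ndarray) -> np.ndarray:
        n = p.size
        order = np.argsort(p, kind="stable")
        adj = np.empty(n)
        running = 1.0
        for rank_from_top in range(n, 0, -1):
            i = order[rank_from_top - 1]
            running = min(running, p[i] * n / rank_from_top)
            adj[i] = running
        return adj

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=60))
    def test_matches_brute_force(self, pvals):
        p = np.asarray(pvals)
        ours = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, self._bh_brute_force(p), atol=1e-12)

    def test_monotone_in_raw_p_order(self, rng):
        p = rng.uniform(size=100)
        adj = multipletests(p, method="fdr_bh")[1]
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        assert (adj >= p - 1e-15).all()


class TestDeFilter:
    def test_threshold_boundaries(self):
        de = pd.DataFrame(
            {"fold_change": [1.19, 5.0, 1.5, 2.0],
             "padj": [0.001, 0.5, 0.009, 0.0001]},
            index=["borderline_fc", "insignificant", "ok1", "ok2"],
        )
        out = de_filter(de, min_fc=1.2, max_adj_p=0.01)
        assert out == ["ok2", "ok1"]  # sorted by descending FC

    def test_recovers_planted_genes(self):
        cfg = SimConfig(n_genes=300, n_blast_cells=200, n_nonblast_cells=200,
                        n_patients=2, planted_log2fc=(2.0,) * 7, seed=8)
        adata = generate_single_cell(cfg)
        norm = lognormalize(adata)
        lab = norm.obs["label"].to_numpy()
        de = wilcoxon_de(norm, lab == "blast", lab == "non-blast")
        hits = de_filter(de)
        planted = set(cfg.planted_genes)
        assert planted <= set(hits)
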