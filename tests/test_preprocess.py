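"""QC filtering, normalization, variable genes and clustering."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import sparse

import ossubtype as ost
from ossubtype.exceptions import ConfigurationError, EmptyResultError


def make_adata(counts, gene_names=None, cell_names=None):
    counts = np.asarray(counts)
    n, g = counts.shape
    return ad.AnnData(
        X=sparse.csr_matrix(counts.astype(np.int32)),
        obs=pd.DataFrame(index=cell_names or [f"c{i}" for i in range(n)]),
        var=pd.DataFrame(index=gene_names or [f"g{j}" for j in range(g)]),
    )


def brute_force_filter(counts, genes, min_cells, max_mito, min_genes, max_genes,
                       ribo_rule="off", ribo_cut=0.05):
    """Independent loop-based application of the genes-then-cells rules."""
    counts = np.asarray(counts)
    keep_genes = [
        j for j in range(counts.shape[1])
        if sum(1 for i in range(counts.shape[0]) if counts[i, j] > 0) >= min_cells
    ]
    sub = counts[:, keep_genes]
    mito = [j for j, name in enumerate(np.asarray(genes)[keep_genes]) if name.startswith("MT-")]
    ribo = [j for j, name in enumerate(np.asarray(genes)[keep_genes])
            if name.startswith(("RPS", "RPL"))]
    keep_cells = []
    for i in range(sub.shape[0]):
        total = sub[i].sum()
        ngenes = int((sub[i] > 0).sum())
        mfrac = sub[i, mito].sum() / total if total > 0 else 0.0
        rfrac = sub[i, ribo].sum() / total if total > 0 else 0.0
        ok = min_genes <= ngenes <= max_genes and mfrac <= max_mito
        if ribo_rule == "remove_below":
            ok = ok and rfrac >= ribo_cut
        elif ribo_rule == "remove_above":
            ok = ok and rfrac <= ribo_cut
        if ok:
            keep_cells.append(i)
    return keep_cells, keep_genes


class TestFilter:
    def test_mito_threshold_boundary(self):
        # cell 0: 25% mito (removed at 20% cutoff), cell 1: 20% (kept)
        genes = ["MT-1", "g1", "g2", "g3"]
        counts = [[25, 25, 25, 25], [20, 30, 25, 25], [10, 30, 30, 30], [5, 30, 30, 35]]
        out = ost.filter_cells_genes(make_adata(counts, genes), min_cells_per_gene=1,
                                     min_genes=1, max_genes=10)
        assert "c0" not in out.obs_names and "c1" in out.obs_names

    def test_gene_detection_boundary(self):
        # g0 detected in 2 cells -> removed; g1 in exactly 3 -> retained
        counts = [[1, 1, 5], [1, 1, 5], [0, 1, 5], [0, 0, 5]]
        out = ost.filter_cells_genes(make_adata(counts), min_cells_per_gene=3,
                                     min_genes=1, max_genes=10)
        assert list(out.var_names) == ["g1", "g2"]

    def test_toy_matrix_matches_brute_force(self):
        rng = np.random.default_rng(0)
        genes = ["MT-1", "RPS9", "g2", "g3", "g4", "g5"]
        counts = rng.integers(0, 6, size=(10, 6))
        counts[3] = [40, 0, 1, 0, 0, 0]   # high mito cell
        counts[4] = [0, 0, 9, 0, 0, 0]    # too few genes
        counts[:, 5] = 0                  # undetected gene
        adata = make_adata(counts, genes)
        out = ost.filter_cells_genes(adata, min_cells_per_gene=3, max_mito_frac=0.2,
                                     min_genes=2, max_genes=5)
        cells, gene_idx = brute_force_filter(counts, genes, 3, 0.2, 2, 5)
        assert list(out.obs_names) == [f"c{i}" for i in cells]
        assert list(out.var_names) == [genes[j] for j in gene_idx]

    @pytest.mark.parametrize("ribo_rule", ["off", "remove_below", "remove_above"])
    @pytest.mark.parametrize("mseed", [1, 2, 3])
    def test_random_matrices_match_brute_force(self, ribo_rule, mseed):
        rng = np.random.default_rng(mseed)
        genes = ["MT-1", "MT-2", "RPS1", "RPL2"] + [f"g{j}" for j in range(8)]
        counts = rng.poisson(1.2, size=(25, 12))
        out_kwargs = dict(min_cells_per_gene=2, max_mito_frac=0.25, min_genes=3,
                          max_genes=9, ribo_rule=ribo_rule, ribo_frac_cut=0.1)
        try:
            out = ost.filter_cells_genes(make_adata(counts, genes), **out_kwargs)
            got = (list(out.obs_names), list(out.var_names))
        except EmptyResultError:
            got = None
        cells, gene_idx = brute_force_filter(counts, genes, 2, 0.25, 3, 9,
                                             ribo_rule=ribo_rule, ribo_cut=0.1)
        if got is None:
            assert not cells or not gene_idx
        else:
            assert got == ([f"c{i}" for i in cells], [genes[j] for j in gene_idx])

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        adata = make_adata(rng.poisson(2, size=(30, 10)))
        once = ost.filter_cells_genes(adata, min_cells_per_gene=3, min_genes=2, max_genes=9)
        twice = ost.filter_cells_genes(once, min_cells_per_gene=3, min_genes=2, max_genes=9)
        assert list(once.obs_names) == list(twice.obs_names)
        assert list(once.var_names) == list(twice.var_names)

    def test_empty_result_raises_with_diagnostics(self):
        counts = [[1, 0], [0, 1], [1, 1]]
        with pytest.raises(EmptyResultError) as exc:
            ost.filter_cells_genes(make_adata(counts), min_cells_per_gene=5,
                                   min_genes=1, max_genes=10)
        assert exc.value.diagnostics["n_genes_in"] == 2

    def test_invalid_thresholds(self):
        with pytest.raises(ConfigurationError):
            ost.filter_cells_genes(make_adata([[1]]), min_genes=10, max_genes=5)


class TestLogNormalize:
    def test_closed_form_value(self):
        # total 100, count 10, scale 10000 -> ln(1 + 1000)
        counts = [[10, 90], [50, 50]]
        norm = ost.lognormalize(make_adata(counts), scale_factor=10000)
        assert norm.X[0, 0] == pytest.approx(np.log(1001.0), abs=1e-9)

    def test_zero_count_maps_to_zero_and_stays_sparse(self):
        norm = ost.lognormalize(make_adata([[0, 5], [3, 2]]))
        assert norm.X[0, 0] == 0.0

    def test_scale_invariance_within_cell(self):
        a = ost.lognormalize(make_adata([[1, 2, 3]]))
        b = ost.lognormalize(make_adata([[2, 4, 6]]))
        assert np.allclose(a.X.toarray(), b.X.toarray())

    def test_zero_total_cell_named_in_error(self):
        with pytest.raises(ValueError, match="c1"):
            ost.lognormalize(make_adata([[1, 2], [0, 0]]))

    def test_preserves_within_cell_rank_order(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(3, size=(10, 20))
        norm = ost.lognormalize(make_adata(counts)).X.toarray()
        for i in range(10):
            assert np.array_equal(np.argsort(counts[i], kind="stable"),
                                  np.argsort(norm[i], kind="stable"))


class TestVariableGenes:
    @staticmethod
    def brute_force_rank(norm):
        """Naive per-gene recomputation of the clipped standardized variance."""
        X = norm.X.toarray()
        n = X.shape[0]
        mean, var = X.mean(0), X.var(0, ddof=1)
        pos = var > 0
        exp_sd = np.ones_like(var)
        coef = np.polyfit(np.log10(mean[pos]), np.log10(var[pos]), 2)
        exp_sd[pos] = np.sqrt(10 ** np.polyval(coef, np.log10(mean[pos])))
        stat = np.zeros_like(var)
        for j in np.flatnonzero(pos):
            z = np.minimum((X[:, j] - mean[j]) / exp_sd[j], np.sqrt(n))
            stat[j] = z.var(ddof=1)
        names = list(norm.var_names)
        return sorted(names, key=lambda g: (-stat[names.index(g)], g))

    def test_matches_brute_force_on_small_matrix(self):
        rng = np.random.default_rng(11)
        counts = rng.negative_binomial(2, 0.3, size=(60, 50))
        norm = ost.lognormalize(make_adata(counts))
        assert ost.select_variable_genes(norm, 20) == self.brute_force_rank(norm)[:20]

    def test_constant_gene_never_precedes_variable(self):
        # equal cell totals keep the constant-count gene constant after normalization
        noisy = np.random.default_rng(0).integers(1, 9, 20)
        counts = np.column_stack([np.full(20, 4), noisy, 20 - noisy])
        norm = ost.lognormalize(make_adata(counts, ["const", "noisy", "noisy2"]))
        assert "const" not in ost.select_variable_genes(norm, 2)

    def test_identity_when_n_equals_genes(self):
        rng = np.random.default_rng(1)
        norm = ost.lognormalize(make_adata(rng.poisson(2, (15, 8)) + 1))
        assert sorted(ost.select_variable_genes(norm, 8)) == sorted(norm.var_names)

    def test_n_too_large_rejected(self):
        norm = ost.lognormalize(make_adata([[1, 2], [3, 4]]))
        with pytest.raises(ValueError):
            ost.select_variable_genes(norm, 3)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        counts = rng.negative_binomial(2, 0.4, size=(40, 30))
        names = [f"g{j:02d}" for j in range(30)]
        norm = ost.lognormalize(make_adata(counts, names))
        perm = rng.permutation(30)
        norm_p = ost.lognormalize(make_adata(counts[:, perm], [names[j] for j in perm]))
        assert ost.select_variable_genes(norm, 10) == ost.select_variable_genes(norm_p, 10)


class TestClustering:
    def test_perfectly_separated_blobs(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(1, size=(30, 10))
        b = rng.poisson(1, size=(30, 10)) + np.array([50] * 5 + [0] * 5)
        adata = make_adata(np.vstack([a + 1, b + 1]))
        norm = ost.lognormalize(adata)
        labels = ost.embed_and_cluster(norm, list(norm.var_names), n_pcs=5, k=2, seed=0)
        truth = [0] * 30 + [1] * 30
        assert ost.ari(labels, truth) == 1.0

    def test_k_one_flagged(self):
        norm = ost.lognormalize(make_adata([[1, 2], [3, 4], [5, 6]]))
        with pytest.warns(UserWarning):
            labels = ost.embed_and_cluster(norm, list(norm.var_names), n_pcs=1, k=1)
        assert set(labels) == {0}

    def test_k_exceeding_cells_rejected(self):
        norm = ost.lognormalize(make_adata([[1, 2], [3, 4]]))
        with pytest.raises(ConfigurationError):
            ost.embed_and_cluster(norm, list(norm.var_names), n_pcs=1, k=5)

    def test_default_synthetic_recovery(self, norm_adata):
        """7 tumor + 3 normal planted clusters recovered at k=10 (ARI >= 0.9)."""
        hvg = ost.select_variable_genes(norm_adata, 1000)
        labels = ost.embed_and_cluster(norm_adata, hvg, n_pcs=30, k=10, seed=1)
        assert ost.ari(labels, norm_adata.obs["true_cluster"]) >= 0.9


class TestClusterFractions:
    def test_from_counts_mapping(self):
        frac = ost.cluster_fractions({"CSC": 369, "other": 45238 - 369})
        assert round(float(frac["CSC"]), 2) == 0.82

    def test_from_label_vector(self):
        frac = ost.cluster_fractions(["a", "a", "b", "b"])
        assert frac["a"] == 50.0


@given(st.lists(st.integers(min_value=1, max_value=50), min_size=4, max_size=12))
def test_normalization_rank_preservation_property(row):
    counts = np.vstack([row, np.ones_like(row)])
    norm = ost.lognormalize(make_adata(counts)).X.toarray()
    order = np.argsort(np.asarray(row), kind="stable")
    assert np.array_equal(order, np.argsort(norm[0], kind="stable"))
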