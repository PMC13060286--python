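"""Homology translation, joint map, alignment scores, gene-pair correlations."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from tubemap import mapping


def hom_table(rows):
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "pident",
                                       "evalue", "bitscore"])


def textbook_pearson(x, y):
    x = np.asarray(x, float) - np.mean(x)
    y = np.asarray(y, float) - np.mean(y)
    return float(np.sum(x * y) / np.sqrt(np.sum(x * x) * np.sum(y * y)))


def make_pm(X, genes=None, graph_k=None):
    """Minimal processed AnnData: log-expression plus optional kNN graph."""
    adata = ad.AnnData(X=np.asarray(X, dtype=float))
    adata.var_names = genes or [f"g{i}" for i in range(X.shape[1])]
    adata.obs_names = [f"c{i}" for i in range(X.shape[0])]
    if graph_k is not None:
        adata.obsm["X_pca"] = np.asarray(X, dtype=float)
        from tubemap import preprocess
        preprocess.build_knn(adata, k=graph_k)
    return adata


class TestTranslation:
    def test_single_hit_gets_weight_one(self):
        t = mapping.build_gene_translation(
            hom_table([("a1", "b1", 90, 1e-30, 150.0)]), source="b")
        assert t.weights[0, 0] == pytest.approx(1.0)

    def test_weights_proportional_to_bitscore(self):
        t = mapping.build_gene_translation(
            hom_table([("a1", "b1", 90, 1e-30, 100.0),
                       ("a2", "b1", 90, 1e-30, 300.0)]), source="b")
        w = t.weights.toarray()[0]
        assert dict(zip(t.target_genes, w)) == pytest.approx(
            {"a1": 0.25, "a2": 0.75})

    def test_weights_sum_to_one_for_every_mapped_gene(self):
        rng = np.random.default_rng(0)
        rows = [(f"a{rng.integers(6)}", f"b{rng.integers(6)}", 90, 1e-30,
                 float(rng.integers(50, 400))) for _ in range(25)]
        t = mapping.build_gene_translation(hom_table(rows), source="b")
        sums = np.asarray(t.weights.sum(axis=1)).ravel()
        assert np.allclose(sums[t.mapped_mask()], 1.0)


class TestJointEmbed:
    def _identity_setup(self, n=30, g=8, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, g)) + 2
        genes = [f"g{i}" for i in range(g)]
        pm_a = make_pm(X, genes, graph_k=4)
        pm_b = make_pm(X.copy(), genes, graph_k=4)
        hom = hom_table([(g_, g_, 95, 1e-40, 100.0) for g_ in genes])
        tr = mapping.build_gene_translation(hom, source="b")
        return pm_a, pm_b, tr, hom

    def test_identity_copy_maps_to_itself(self):
        pm_a, pm_b, tr, hom = self._identity_setup()
        jm = mapping.joint_embed(pm_a, pm_b, tr, k_cross=3, homology=hom)
        assert (jm.nbrs_ab[:, 0] == np.arange(pm_a.n_obs)).all()
        assert (jm.nbrs_ba[:, 0] == np.arange(pm_b.n_obs)).all()
        assert np.allclose(jm.dist_ab[:, 0], 0.0, atol=1e-6)

    def test_neighbors_match_brute_force(self):
        """Full-rank joint PCA is an isometry, so neighbor sets must equal a
        brute-force search in the z-scored translated space."""
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(6)]
        pm_a = make_pm(rng.normal(size=(40, 6)), genes)
        pm_b = make_pm(rng.normal(size=(40, 6)), genes)
        hom = hom_table([(g_, g_, 95, 1e-40, 100.0) for g_ in genes])
        tr = mapping.build_gene_translation(hom, source="b")
        k = 5
        jm = mapping.joint_embed(pm_a, pm_b, tr, k_cross=k, homology=hom,
                                 n_joint_pcs=6)
        Za = mapping._zscore_cols(np.asarray(pm_a.X))
        Zb = mapping._zscore_cols(np.asarray(pm_b.X))
        d2 = ((Za[:, None, :] - Zb[None, :, :]) ** 2).sum(-1)
        for i in range(40):
            assert set(jm.nbrs_ab[i]) == set(np.argsort(d2[i])[:k])
        for j in range(40):
            assert set(jm.nbrs_ba[j]) == set(np.argsort(d2[:, j])[:k])

    def test_deterministic(self):
        pm_a, pm_b, tr, hom = self._identity_setup(seed=2)
        jm1 = mapping.joint_embed(pm_a, pm_b, tr, k_cross=3, homology=hom)
        jm2 = mapping.joint_embed(pm_a, pm_b, tr, k_cross=3, homology=hom)
        assert (jm1.nbrs_ab == jm2.nbrs_ab).all()
        assert np.array_equal(jm1.dist_ba, jm2.dist_ba)

    def test_empty_translation_raises(self):
        pm_a = make_pm(np.ones((5, 3)))
        pm_b = make_pm(np.ones((5, 3)), genes=["x0", "x1", "x2"])
        hom = hom_table([("zz", "yy", 90, 1e-30, 50.0)])
        tr = mapping.build_gene_translation(hom, source="b")
        with pytest.raises(ValueError, match="translation"):
            mapping.joint_embed(pm_a, pm_b, tr, k_cross=2)


class TestAlignmentScores:
    def _jm_identity_clusters(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 0.2, (20, 5)),
                       rng.normal(5, 0.2, (20, 5))])
        genes = [f"g{i}" for i in range(5)]
        pm_a = make_pm(X, genes, graph_k=4)
        pm_b = make_pm(X.copy(), genes, graph_k=4)
        hom = hom_table([(g_, g_, 95, 1e-40, 100.0) for g_ in genes])
        tr = mapping.build_gene_translation(hom, source="b")
        jm = mapping.joint_embed(pm_a, pm_b, tr, k_cross=5, homology=hom)
        labels = np.array(["u"] * 20 + ["v"] * 20)
        return jm, labels

    def test_saturated_and_empty_pairs(self):
        jm, labels = self._jm_identity_clusters()
        mat, best = mapping.alignment_scores(jm, labels, labels)
        assert mat.loc["u", "u"] == pytest.approx(1.0)
        assert mat.loc["v", "v"] == pytest.approx(1.0)
        assert mat.loc["u", "v"] == pytest.approx(0.0)
        assert ((mat.to_numpy() >= 0) & (mat.to_numpy() <= 1)).all()
        amax = best[best["side"] == "a"].set_index("cluster")["best_match"]
        assert amax["u"] == "u" and amax["v"] == "v"

    def test_invariant_under_label_permutation(self):
        jm, labels = self._jm_identity_clusters()
        mat, _ = mapping.alignment_scores(jm, labels, labels)
        renamed = np.where(labels == "u", "z_late", "a_early")
        mat2, _ = mapping.alignment_scores(jm, renamed, renamed)
        assert mat2.loc["z_late", "z_late"] == pytest.approx(
            mat.loc["u", "u"])
        assert mat2.loc["a_early", "z_late"] == pytest.approx(
            mat.loc["v", "u"])

    def test_label_length_mismatch_raises(self):
        jm, labels = self._jm_identity_clusters()
        with pytest.raises(ValueError):
            mapping.alignment_scores(jm, labels[:-1], labels)


class TestSmoothing:
    def test_neighbors_sharing_value_are_fixed_point(self):
        adata = make_pm(np.full((6, 2), 3.7), graph_k=2)
        sm = mapping.smooth_expression(adata)
        assert np.allclose(sm, 3.7)

    def test_matrix_form_oracle_on_five_nodes(self):
        adata = make_pm(np.arange(10).reshape(5, 2).astype(float))
        # path graph 0-1-2-3-4 with unit weights
        rows = [0, 1, 1, 2, 2, 3, 3, 4]
        cols = [1, 0, 2, 1, 3, 2, 4, 3]
        adata.obsp["distances"] = sp.csr_matrix(
            (np.ones(8), (rows, cols)), shape=(5, 5))
        sm = mapping.smooth_expression(adata)
        A = adata.obsp["distances"].toarray() + np.eye(5)
        expected = np.diag(1.0 / A.sum(1)) @ A @ np.asarray(adata.X)
        assert np.allclose(sm, expected)

    def test_global_mean_preserved_on_regular_graph(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 3))
        adata = make_pm(X)
        # 6-cycle: every node has degree 2 (regular)
        rows, cols = [], []
        for i in range(6):
            rows += [i, (i + 1) % 6]
            cols += [(i + 1) % 6, i]
        adata.obsp["distances"] = sp.csr_matrix(
            (np.ones(12), (rows, cols)), shape=(6, 6))
        sm = mapping.smooth_expression(adata)
        assert np.allclose(sm.mean(axis=0), X.mean(axis=0))


class TestGenePairCorrelation:
    def _jm(self, seed=0, n=30, g=6):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(g)]
        pm_a = make_pm(rng.normal(size=(n, g)) + 3, genes, graph_k=4)
        pm_b = make_pm(rng.normal(size=(n, g)) + 3, genes, graph_k=4)
        hom = hom_table([(g_, g_, 95, 1e-40, 100.0) for g_ in genes])
        tr = mapping.build_gene_translation(hom, source="b")
        return mapping.joint_embed(pm_a, pm_b, tr, k_cross=4, homology=hom)

    def test_matches_textbook_pearson(self):
        """Directional correlations equal the direct formula to 1e-10."""
        jm = self._jm()
        genes = list(jm.adata_a.var_names)
        SA = mapping.smooth_expression(jm.adata_a, genes)
        IB = mapping._impute_cross(jm.adata_b, jm.nbrs_ab, genes)
        C_a, _ = mapping.pair_correlations(jm, genes, genes)
        for i in range(len(genes)):
            for j in range(len(genes)):
                assert C_a[i, j] == pytest.approx(
                    textbook_pearson(SA[:, i], IB[:, j]), abs=1e-10)

    def test_symmetric_value_is_mean_of_directions(self):
        jm = self._jm(seed=1)
        C_a, C_b = mapping.pair_correlations(jm, ["g0"], ["g1"])
        sym = mapping.gene_pair_correlation(jm, "g0", "g1")
        assert sym == pytest.approx(0.5 * (C_a[0, 0] + C_b[0, 0]))

    def test_constant_gene_returns_flagged_null(self):
        jm = self._jm(seed=2)
        jm.adata_a.X[:, 0] = 1.0
        assert mapping.gene_pair_correlation(jm, "g0", "g1") is None

    def test_unknown_gene_raises(self):
        jm = self._jm(seed=3)
        with pytest.raises(KeyError):
            mapping.gene_pair_correlation(jm, "nope", "g1")


class TestFindGenePairs:
    def test_threshold_is_strict_and_output_is_subset(self):
        jm = TestGenePairCorrelation()._jm(seed=5)
        cand = [("g0", "g1"), ("g2", "g3")]
        c01 = mapping.gene_pair_correlation(jm, "g0", "g1")
        out_at = mapping.find_gene_pairs(jm, min_corr=c01, candidates=cand)
        assert ("g0", "g1") not in set(zip(out_at.gene_a, out_at.gene_b))
        out_below = mapping.find_gene_pairs(jm, min_corr=c01 - 1e-9,
                                            candidates=cand)
        assert ("g0", "g1") in set(zip(out_below.gene_a, out_below.gene_b))
        full = mapping.find_gene_pairs(jm, min_corr=-1.1, candidates=cand)
        assert set(zip(full.gene_a, full.gene_b)) <= set(cand)

    def test_homology_annotation(self):
        jm = TestGenePairCorrelation()._jm(seed=6)
        out = mapping.find_gene_pairs(jm, min_corr=-1.1,
                                      candidates=[("g0", "g0"),
                                                  ("g0", "g1")])
        rec = out.set_index(["gene_a", "gene_b"])
        assert rec.loc[("g0", "g0"), "inverse_bitscore"] == pytest.approx(
            1 / 100.0)
        assert np.isinf(rec.loc[("g0", "g1"), "inverse_bitscore"])
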