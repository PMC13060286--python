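"""QC, normalization, feature selection, embedding, clustering, markers."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import scipy.stats

from tubemap import preprocess as pp
from conftest import make_counts_adata


def brute_force_u(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of sample x by exhaustive pair counting (ties = 1/2)."""
    u = 0.0
    for xi in x:
        for yj in y:
            u += 1.0 if xi > yj else (0.5 if xi == yj else 0.0)
    return u


class TestQCFilter:
    def _fixture(self):
        # 6 cells x 5 genes, gene 0 mitochondrial; totals 1000 unless noted
        counts = np.array([
            [300, 175, 175, 175, 175],   # mito 0.30 exactly -> kept
            [310, 173, 173, 172, 172],   # mito 0.31 -> removed
            [0, 187, 187, 187, 188],     # counts 749 -> removed
            [0, 188, 187, 187, 188],     # counts 750 exactly -> kept
            [0, 1000, 0, 0, 0],          # 1 feature -> removed
            [100, 225, 225, 225, 225],   # clean -> kept
        ])
        return make_counts_adata(counts, mito_mask=[1, 0, 0, 0, 0])

    def test_planted_violations_removed_exactly(self):
        adata = self._fixture()
        kept, report = pp.qc_filter(adata, mito_max=0.30, min_counts=750,
                                    min_features=3)
        assert set(report["removed_cells"]) == {"c001", "c002", "c004"}
        assert list(kept.obs_names) == ["c000", "c003", "c005"]
        assert report["removed_mito"] == 1
        assert report["removed_counts"] == 1
        assert report["removed_features"] == 1

    @pytest.mark.parametrize("loose", [
        dict(mito_max=0.50), dict(min_counts=100), dict(min_features=1),
        dict(mito_max=0.95, min_counts=0, min_features=0)])
    def test_loosening_thresholds_is_monotone(self, loose):
        """No cell kept under strict thresholds is removed under looser ones."""
        strict = dict(mito_max=0.30, min_counts=750, min_features=3)
        kept_strict, _ = pp.qc_filter(self._fixture(), **strict)
        kept_loose, _ = pp.qc_filter(self._fixture(), **{**strict, **loose})
        assert set(kept_strict.obs_names) <= set(kept_loose.obs_names)

    def test_all_cells_removed_is_an_error(self):
        with pytest.raises(pp.QCError, match="every cell"):
            pp.qc_filter(self._fixture(), mito_max=0.0, min_counts=10**6,
                         min_features=10**6)


class TestNormalizeLog:
    def test_proportional_scaling(self):
        adata = make_counts_adata(np.array([[2, 2, 0, 0]]))
        pp.normalize_log(adata, scale=1e4)
        pre_log = np.expm1(np.asarray(adata.X))
        assert np.allclose(pre_log, [[5000, 5000, 0, 0]])

    def test_equal_count_cells_normalize_identically(self):
        adata = make_counts_adata(np.array([[5, 5, 5], [7, 7, 7]]))
        pp.normalize_log(adata)
        X = np.asarray(adata.X)
        assert np.allclose(X[0], X[1])

    def test_inverse_transform_resums_to_scale(self):
        rng = np.random.default_rng(0)
        adata = make_counts_adata(rng.integers(1, 50, size=(20, 30)))
        pp.normalize_log(adata, scale=1e4)
        sums = np.expm1(np.asarray(adata.X)).sum(axis=1)
        assert np.allclose(sums, 1e4, atol=1e-8)

    def test_zero_total_cell_named(self):
        adata = make_counts_adata(np.array([[1, 1], [0, 0]]))
        with pytest.raises(pp.QCError, match="c001"):
            pp.normalize_log(adata)


class TestSelectHVG:
    def _lognorm(self, counts):
        adata = make_counts_adata(counts)
        return pp.normalize_log(adata)

    def test_constant_gene_never_flagged(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 30, size=(30, 10))
        counts[:, 3] = 0  # constant zero after normalization
        adata = pp.select_hvg(self._lognorm(counts), n_hvg=9)
        assert not adata.var["highly_variable"].iloc[3]

    def test_all_nonconstant_flagged_when_n_hvg_large(self):
        rng = np.random.default_rng(1)
        adata = pp.select_hvg(self._lognorm(rng.integers(1, 30, (25, 8))),
                              n_hvg=8)
        assert adata.var["highly_variable"].sum() == 8


class TestEmbedPCA:
    def test_exact_rank_two_input_keeps_two_components(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 12))
        weights = rng.normal(size=(50, 2))
        X = weights @ basis
        adata = ad.AnnData(X=X)
        adata.var_names = [f"g{i}" for i in range(12)]
        adata.var["highly_variable"] = True
        pp.embed_pca(adata, variance_target=0.999, max_components=10, seed=0)
        assert adata.obsm["X_pca"].shape[1] == 2

    def test_variance_accounting(self):
        rng = np.random.default_rng(2)
        adata = ad.AnnData(X=rng.normal(size=(60, 20)))
        adata.var["highly_variable"] = True
        pp.embed_pca(adata, variance_target=0.95, max_components=15, seed=0)
        ratios = adata.uns["pca_variance_ratio"]
        assert np.all(np.diff(ratios) <= 1e-12)  # non-increasing
        assert ratios.sum() >= 0.95 or len(ratios) == 15


class TestBuildKnn:
    def _adata(self, points):
        adata = ad.AnnData(X=np.zeros((len(points), 2)))
        adata.obsm["X_pca"] = np.asarray(points, dtype=float)
        return adata

    def test_collinear_union_symmetrization(self):
        adata = self._adata([[0.0, 0], [1.0, 0], [10.0, 0]])
        pp.build_knn(adata, k=1)
        g = adata.obsp["distances"]
        assert g[1, 0] > 0 and g[0, 1] > 0   # middle joins nearer endpoint
        assert g[2, 1] > 0 and g[1, 2] > 0   # far point's edge symmetrized
        assert g.diagonal().sum() == 0

    def test_degree_at_least_k(self):
        rng = np.random.default_rng(0)
        adata = self._adata(rng.normal(size=(40, 3)))
        pp.build_knn(adata, k=5)
        deg = (adata.obsp["distances"] > 0).sum(axis=1)
        assert (np.asarray(deg).ravel() >= 5).all()

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(50, 4))
        adata = self._adata(pts)
        k = 6
        pp.build_knn(adata, k=k)
        g = adata.obsp["distances"]
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        directed = set()
        for i in range(50):
            for j in np.argsort(d2[i])[:k]:
                directed.add((i, int(j)))
        expected = directed | {(j, i) for i, j in directed}
        got = set(zip(*g.nonzero()))
        assert got == expected

    def test_k_too_large_raises(self):
        with pytest.raises(ValueError):
            pp.build_knn(self._adata(np.zeros((3, 2))), k=3)


class TestCluster:
    def test_two_blobs_recovered_exactly(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.3, size=(40, 3)),
                         rng.normal(8, 0.3, size=(40, 3))])
        adata = ad.AnnData(X=np.zeros((80, 2)))
        adata.obsm["X_pca"] = pts
        pp.build_knn(adata, k=10)
        pp.cluster(adata, resolution=0.7, seed=0)
        labels = adata.obs["cluster"].to_numpy()
        assert len(set(labels)) == 2
        assert len(set(labels[:40])) == 1 and len(set(labels[40:])) == 1
        assert labels[0] != labels[-1]

    def test_same_seed_identical(self):
        rng = np.random.default_rng(1)
        adata = ad.AnnData(X=np.zeros((60, 2)))
        adata.obsm["X_pca"] = rng.normal(size=(60, 5))
        pp.build_knn(adata, k=8)
        l1 = pp.cluster(adata, resolution=0.7, seed=3).obs["cluster"].copy()
        l2 = pp.cluster(adata, resolution=0.7, seed=3).obs["cluster"].copy()
        assert (l1 == l2).all()


class TestWilcoxonMarkers:
    def test_fully_separating_gene_has_extreme_u(self):
        X = np.zeros((10, 2))
        X[:4, 0] = [5.0, 6.0, 7.0, 8.0]  # cluster values all above rest
        mask = np.array([True] * 4 + [False] * 6)
        u, p = pp.mann_whitney_u(X, mask)
        assert u[0] == 4 * 6
        assert p[0] < 0.01

    @pytest.mark.parametrize("n1,n2", [(2, 3), (4, 4), (5, 8), (8, 8)])
    def test_u_equals_exhaustive_enumeration_with_ties(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(5):
            x = rng.integers(0, 3, n1).astype(float)
            y = rng.integers(0, 3, n2).astype(float)
            X = np.concatenate([x, y])[:, None]
            mask = np.array([True] * n1 + [False] * n2)
            u, _ = pp.mann_whitney_u(X, mask)
            assert u[0] == pytest.approx(brute_force_u(x, y))

    def test_matches_scipy_with_tie_correction(self):
        """Independent oracle: scipy's asymptotic Mann-Whitney p-values."""
        rng = np.random.default_rng(0)
        X = np.round(rng.normal(size=(40, 6)), 1)
        mask = np.zeros(40, bool)
        mask[:15] = True
        u, p = pp.mann_whitney_u(X, mask)
        for j in range(6):
            ref = scipy.stats.mannwhitneyu(
                X[mask, j], X[~mask, j], alternative="two-sided",
                method="asymptotic", use_continuity=False)
            assert u[j] == pytest.approx(ref.statistic)
            assert p[j] == pytest.approx(ref.pvalue, rel=1e-10)

    def test_bh_adjustment_monotone_within_cluster(self):
        rng = np.random.default_rng(4)
        adata = make_counts_adata(rng.integers(0, 20, size=(30, 12)))
        pp.normalize_log(adata)
        labels = np.array(["x"] * 15 + ["y"] * 15)
        table = pp.rank_markers_wilcoxon(adata, labels=labels)
        assert ((table["adjusted_p"] >= table["p_value"]) |
                np.isclose(table["adjusted_p"], table["p_value"])).all()
        for _, sub in table.groupby("cluster"):
            s = sub.sort_values("p_value")
            assert (np.diff(s["adjusted_p"]) >= -1e-12).all()
        assert ((table["p_value"] > 0) & (table["p_value"] <= 1)).all()


class TestComposition:
    def test_proportions(self):
        meta = pd.DataFrame({"grp": ["g1", "g1", "g1", "g2"],
                             "lab": ["a", "a", "b", "b"]})
        out = pp.composition(meta, "grp", "lab")
        assert out.loc["g1", "a"] == pytest.approx(2 / 3)
        assert out.loc["g1", "b"] == pytest.approx(1 / 3)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-12)

    def test_counts_match_exhaustive_tally(self):
        rng = np.random.default_rng(5)
        meta = pd.DataFrame({"grp": rng.choice(["p", "q", "r"], 100),
                             "lab": rng.choice(["a", "b"], 100)})
        out = pp.composition(meta, "grp", "lab")
        for g in ("p", "q", "r"):
            sub = meta[meta["grp"] == g]
            for l in ("a", "b"):
                assert out.loc[g, l] == pytest.approx(
                    (sub["lab"] == l).mean())

    def test_missing_column_raises(self):
        with pytest.raises(KeyError):
            pp.composition(pd.DataFrame({"grp": ["a"]}), "grp", "lab")
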