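"""Per-species QC, normalization, feature selection, embedding, clustering.

The processed state lives on the AnnData: raw counts in
``layers["counts"]``, log-normalized expression in ``X``,
``var["highly_variable"]`` / ``var["dispersion_std"]``, the PCA embedding in
``obsm["X_pca"]`` with ``uns["pca_variance_ratio"]``, the symmetrized kNN
graph (Euclidean edge weights) in ``obsp["distances"]`` and cluster labels
in ``obs["cluster"]``.
"""

from __future__ import annotations

import logging

import anndata as ad
import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)


class QCError(ValueError):
    pass


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


def qc_metrics(adata: ad.AnnData) -> pd.DataFrame:
    """Per-cell total counts, detected features and mitochondrial fraction."""
    X = adata.layers.get("counts", adata.X)
    total = np.asarray(X.sum(axis=1)).ravel()
    n_features = np.asarray((X > 0).sum(axis=1)).ravel()
    if "is_mito" not in adata.var.columns:
        raise QCError("gene_meta.is_mito must be populated before QC")
    mito_mask = adata.var["is_mito"].to_numpy(dtype=bool)
    mito = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 1.0)
    return pd.DataFrame({"total_counts": total, "n_features": n_features,
                         "mito_fraction": mito_frac}, index=adata.obs_names)


def qc_filter(adata: ad.AnnData, mito_max: float = 0.30,
              min_counts: int = 750, min_features: int = 200
              ) -> tuple[ad.AnnData, dict]:
    """Remove low-quality cells under strict inequalities.

    A cell is removed when mito_fraction > ``mito_max`` OR total counts <
    ``min_counts`` OR detected genes < ``min_features`` — strictly, so a cell
    at exactly the mitochondrial cap or exactly the count floor is kept.
    Loosening any threshold can therefore never remove a previously kept
    cell. Returns the filtered matrix and a report with removal counts per
    criterion (a cell may trip several).
    """
    m = qc_metrics(adata)
    fail_mito = (m["mito_fraction"] > mito_max).to_numpy()
    fail_counts = (m["total_counts"] < min_counts).to_numpy()
    fail_features = (m["n_features"] < min_features).to_numpy()
    removed = fail_mito | fail_counts | fail_features
    report = {
        "n_input": adata.n_obs,
        "removed_mito": int(fail_mito.sum()),
        "removed_counts": int(fail_counts.sum()),
        "removed_features": int(fail_features.sum()),
        "n_removed": int(removed.sum()),
        "n_kept": int((~removed).sum()),
        "removed_cells": adata.obs_names[removed].tolist(),
        "thresholds": {"mito_max": mito_max, "min_counts": min_counts,
                       "min_features": min_features},
    }
    if report["n_kept"] == 0:
        raise QCError("QC removed every cell; thresholds "
                      f"{report['thresholds']} are incompatible with the data")
    out = adata[~removed].copy()
    out.obs["total_counts"] = m.loc[out.obs_names, "total_counts"].to_numpy()
    out.obs["n_features"] = m.loc[out.obs_names, "n_features"].to_numpy()
    out.obs["mito_fraction"] = m.loc[out.obs_names, "mito_fraction"].to_numpy()
    logger.info("QC kept %d/%d cells (mito %d, counts %d, features %d removed)",
                report["n_kept"], report["n_input"], report["removed_mito"],
                report["removed_counts"], report["removed_features"])
    return out, report


def normalize_log(adata: ad.AnnData, scale: float = 1e4) -> ad.AnnData:
    """Counts-per-``scale`` normalization followed by log(1 + x), in place.

    Raw counts are preserved in ``layers["counts"]``. Before the log, every
    cell's values sum to ``scale`` exactly. Zero-total cells (which QC should
    have removed) raise an error naming the cell.
    """
    counts = _dense(adata.X).astype(float)
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        bad = adata.obs_names[totals == 0][:5].tolist()
        raise QCError(f"zero-total cells cannot be normalized: {bad}")
    adata.layers["counts"] = sp.csr_matrix(adata.X)
    adata.X = np.log1p(counts / totals[:, None] * scale)
    return adata


def select_hvg(adata: ad.AnnData, n_hvg: int = 2000,
               n_mean_bins: int = 20) -> ad.AnnData:
    """Flag highly variable genes by mean-binned standardized dispersion.

    Dispersion = variance / mean of the log-normalized expression; genes are
    binned into ``n_mean_bins`` equal-frequency mean bins and the dispersion
    is z-scored within each bin. The ``n_hvg`` genes with the largest
    standardized dispersion win; ties break lexicographically on gene id.
    Constant genes are never flagged; when fewer than ``n_hvg`` non-constant
    genes exist all of them are flagged with a warning.
    """
    X = _dense(adata.X)
    mean = X.mean(axis=0)
    var = X.var(axis=0)
    nonconst = var > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)

    disp_std = np.zeros(adata.n_vars)
    order = np.argsort(mean, kind="stable")
    bins = np.array_split(order, n_mean_bins)
    for b in bins:
        if len(b) == 0:
            continue
        d = disp[b]
        mu, sd = d.mean(), d.std()
        disp_std[b] = (d - mu) / sd if sd > 0 else 0.0
    disp_std[~nonconst] = -np.inf

    n_avail = int(nonconst.sum())
    n_take = min(n_hvg, n_avail)
    if n_avail < n_hvg:
        logger.warning("only %d non-constant genes available for n_hvg=%d; "
                       "flagging all of them", n_avail, n_hvg)
    ranking = sorted(range(adata.n_vars),
                     key=lambda i: (-disp_std[i], adata.var_names[i]))
    flags = np.zeros(adata.n_vars, dtype=bool)
    flags[ranking[:n_take]] = True
    adata.var["dispersion_std"] = disp_std
    adata.var["highly_variable"] = flags
    return adata


def embed_pca(adata: ad.AnnData, variance_target: float = 0.95,
              max_components: int = 100, seed: int = 0) -> ad.AnnData:
    """PCA of z-scored highly variable genes, truncated at a variance target.

    Up to ``max_components`` components are computed; the smallest leading
    set whose cumulative share of the computed components' variance reaches
    ``variance_target`` is kept (at least one). Per-component explained
    variance ratios (relative to the computed components) are stored in
    ``uns["pca_variance_ratio"]``.
    """
    hv = adata.var["highly_variable"].to_numpy(dtype=bool)
    X = _dense(adata.X)[:, hv]
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    n_comp = min(max_components, min(Z.shape) - 1)
    n_comp = max(n_comp, 1)
    pca = PCA(n_components=n_comp, svd_solver="randomized",
              random_state=seed)
    Y = pca.fit_transform(Z)

    var = pca.explained_variance_
    share = var / var.sum()
    m = int(np.searchsorted(np.cumsum(share), variance_target) + 1)
    m = max(1, min(m, n_comp))
    adata.obsm["X_pca"] = Y[:, :m]
    adata.uns["pca_variance_ratio"] = share[:m]
    adata.uns["pca_n_components_computed"] = n_comp
    logger.info("PCA kept %d/%d components (%.1f%% of computed variance)",
                m, n_comp, 100 * share[:m].sum())
    return adata


def build_knn(adata: ad.AnnData, k: int = 70) -> ad.AnnData:
    """Symmetrized k-nearest-neighbor graph in embedding space.

    Each cell is joined to its ``k`` nearest Euclidean neighbors; the edge
    set is the union with its reverse, stored as a symmetric sparse matrix of
    Euclidean distances in ``obsp["distances"]``. No self-loops; every cell
    has degree >= k after the union.
    """
    emb = adata.obsm["X_pca"]
    n = emb.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells {n}")
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="brute").fit(emb)
    dist, idx = nn.kneighbors(emb)
    # drop each cell's self column (distance 0, first by sort stability)
    rows = np.repeat(np.arange(n), k)
    self_mask = idx == np.arange(n)[:, None]
    # guard against duplicate points: ensure exactly one drop per row
    keep = np.ones_like(idx, dtype=bool)
    for i in range(n):
        j = np.flatnonzero(self_mask[i])
        drop = j[0] if len(j) else 0
        keep[i, drop] = False
    cols = idx[keep]
    vals = dist[keep]
    g = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    g = g.maximum(g.T)  # union symmetrization keeps the Euclidean weight
    adata.obsp["distances"] = g
    return adata


def cluster(adata: ad.AnnData, resolution: float = 0.7,
            seed: int = 0) -> ad.AnnData:
    """Leiden community detection on the kNN graph (RB-configuration
    modularity at the given resolution), labels ordered by descending size.

    Deterministic for a fixed seed; labels are consecutive integers starting
    at 0, cluster 0 being the largest.
    """
    g = adata.obsp["distances"]
    coo = sp.triu(g, k=1).tocoo()
    graph = igraph.Graph(n=g.shape[0],
                         edges=list(zip(coo.row.tolist(), coo.col.tolist())))
    part = leidenalg.find_partition(
        graph, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=int(seed), n_iterations=2)
    labels = np.asarray(part.membership)
    sizes = pd.Series(labels).value_counts()
    remap = {old: new for new, old in enumerate(sizes.index)}
    labels = np.array([remap[l] for l in labels])
    adata.obs["cluster"] = pd.Categorical(labels.astype(str),
                                          categories=[str(i) for i in
                                                      range(labels.max() + 1)])
    logger.info("leiden resolution=%.2f -> %d clusters", resolution,
                labels.max() + 1)
    return adata


def _tie_term(X: np.ndarray) -> np.ndarray:
    """Per-gene sum of t^3 - t over tied groups (for the U variance)."""
    n, g = X.shape
    out = np.zeros(g)
    S = np.sort(X, axis=0)
    for j in range(g):
        col = S[:, j]
        # run lengths of equal values
        change = np.flatnonzero(np.diff(col) != 0)
        starts = np.concatenate(([0], change + 1))
        ends = np.concatenate((change + 1, [n]))
        t = ends - starts
        t = t[t > 1]
        out[j] = np.sum(t ** 3 - t)
    return out


def mann_whitney_u(X: np.ndarray, mask: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-vs-rest Mann–Whitney U with tie-corrected normal p.

    ``X`` is cells x genes; ``mask`` selects the in-group cells. Returns the
    U statistic of the in-group and a two-sided p-value from the normal
    approximation with tie correction (no continuity correction).
    """
    n = X.shape[0]
    n1 = int(mask.sum())
    n2 = n - n1
    ranks = scipy.stats.rankdata(X, axis=0)
    r1 = ranks[mask].sum(axis=0)
    u = r1 - n1 * (n1 + 1) / 2.0

    mu = n1 * n2 / 2.0
    tie = _tie_term(X)
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    sigma = np.sqrt(np.maximum(sigma2, 0))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sigma > 0, (u - mu) / np.maximum(sigma, 1e-300), 0.0)
    p = 2.0 * scipy.stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return u, p


def rank_markers_wilcoxon(adata: ad.AnnData, labels=None,
                          pseudocount: float = 1e-9) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum marker test per cluster.

    For every (cluster, gene): the U statistic and tie-corrected normal
    approximation p-value, a log2 fold change of expm1-means with a
    pseudocount, and Benjamini–Hochberg adjusted p-values computed within
    each cluster's gene family. Clusters of fewer than 2 cells are skipped
    with a warning.
    """
    if labels is None:
        labels = adata.obs["cluster"]
    labels = np.asarray(labels).astype(str)
    groups = sorted(pd.unique(labels))
    if len(groups) < 2:
        raise ValueError("need at least 2 clusters for marker detection")
    X = _dense(adata.X)
    expm1 = np.expm1(X)

    frames = []
    for grp in groups:
        mask = labels == grp
        if mask.sum() < 2:
            logger.warning("cluster %s has <2 cells; skipped", grp)
            continue
        u, p = mann_whitney_u(X, mask)
        m1 = expm1[mask].mean(axis=0)
        m2 = expm1[~mask].mean(axis=0)
        lfc = np.log2((m1 + pseudocount) / (m2 + pseudocount))
        adj = scipy.stats.false_discovery_control(p, method="bh")
        frames.append(pd.DataFrame({
            "gene": adata.var_names, "cluster": grp, "log_fold_change": lfc,
            "u_statistic": u, "p_value": p, "adjusted_p": np.maximum(adj, p),
        }))
    return pd.concat(frames, ignore_index=True)


def composition(cell_meta: pd.DataFrame, group_col: str,
                label_col: str) -> pd.DataFrame:
    """Per-group label proportions (each group's row sums to 1)."""
    for col in (group_col, label_col):
        if col not in cell_meta.columns:
            raise KeyError(f"column {col!r} not in cell metadata")
    counts = pd.crosstab(cell_meta[group_col], cell_meta[label_col])
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("empty group in composition table")
    return counts.div(counts.sum(axis=1), axis=0)


def annotate_clusters(labels, states) -> dict:
    """Map each cluster label to the majority state among its cells."""
    df = pd.DataFrame({"cluster": np.asarray(labels).astype(str),
                       "state": np.asarray(states)})
    maj = (df.groupby("cluster", observed=True)["state"]
             .agg(lambda s: s.value_counts().index[0]))
    return maj.to_dict()
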