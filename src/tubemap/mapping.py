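"""Homology-seeded cross-species alignment.

A deliberately single-round simplification of iterative manifold-alignment
pipelines: species-B expression is translated into species-A gene space
through a bitscore-weighted bipartite homology map, the shared dimensions
are z-scored per species, and k cross-species nearest neighbors are taken
each way. From the cross-neighbor lists come

* cluster-pair **alignment scores** in [0, 1] — the symmetrized mean
  fraction of cross-neighbors falling in the partner cluster — with the
  best-match (Sankey-style) pairing, and
* **gene-pair correlations** — the Pearson correlation between a gene's
  neighborhood-smoothed expression on its own species and the partner
  gene's expression imputed across species as the unweighted mean over
  cross-neighbors; the symmetric value averages both directions.

Numeric equality with any particular published alignment tool is not
promised; the semantics of its outputs are.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)


@dataclass
class Translation:
    """Weighted bipartite gene map (source species -> target species)."""

    source_genes: list
    target_genes: list
    weights: sp.csr_matrix  # n_source x n_target, rows sum to 1 where mapped

    def mapped_mask(self) -> np.ndarray:
        return np.asarray(self.weights.sum(axis=1)).ravel() > 0


def build_gene_translation(homology: pd.DataFrame, source: str = "b"
                           ) -> Translation:
    """Bitscore-proportional translation weights from a homology table.

    For every source gene the outgoing weights over its hits are
    proportional to bitscore and normalized to sum to 1; genes absent from
    the table have an empty translation row.
    """
    src_col, tgt_col = ("gene_b", "gene_a") if source == "b" else ("gene_a",
                                                                   "gene_b")
    src_genes = sorted(homology[src_col].unique())
    tgt_genes = sorted(homology[tgt_col].unique())
    src_index = {g: i for i, g in enumerate(src_genes)}
    tgt_index = {g: i for i, g in enumerate(tgt_genes)}
    rows = homology[src_col].map(src_index).to_numpy()
    cols = homology[tgt_col].map(tgt_index).to_numpy()
    w = sp.csr_matrix((homology["bitscore"].to_numpy(), (rows, cols)),
                      shape=(len(src_genes), len(tgt_genes)))
    row_sums = np.asarray(w.sum(axis=1)).ravel()
    inv = np.zeros_like(row_sums)
    inv[row_sums > 0] = 1.0 / row_sums[row_sums > 0]
    w = sp.diags(inv) @ w
    return Translation(src_genes, tgt_genes, w.tocsr())


@dataclass
class JointMap:
    """Cross-species neighbor structure over a shared translated gene space."""

    adata_a: ad.AnnData
    adata_b: ad.AnnData
    shared_genes: list        # species-A gene ids spanning the shared space
    translation: Translation  # B -> A
    homology: pd.DataFrame
    nbrs_ab: np.ndarray       # (n_a, k): indices of B cells nearest each A cell
    dist_ab: np.ndarray
    nbrs_ba: np.ndarray       # (n_b, k)
    dist_ba: np.ndarray


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


def _zscore_cols(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def joint_embed(pm_a: ad.AnnData, pm_b: ad.AnnData,
                translation: Translation, k_cross: int = 20,
                homology: pd.DataFrame | None = None,
                n_joint_pcs: int = 100) -> JointMap:
    """Place both species in the translated shared space and link them.

    Species-B log-normalized expression is pushed through the B->A
    translation; the shared dimensions (species-A genes reachable through
    the map and present in ``pm_a``) are z-scored within each species and
    the stacked matrix is reduced to ``n_joint_pcs`` principal components
    (denoising the neighbor search, as joint-embedding integration methods
    do); every cell receives its ``k_cross`` nearest cross-species
    Euclidean neighbors in that space. Raises if the translation maps no
    genes.
    """
    src_in_b = [g for g in translation.source_genes if g in pm_b.var_names]
    if not src_in_b:
        raise ValueError("empty translation: no source genes present in "
                         "species-B matrix")
    src_idx = [translation.source_genes.index(g) for g in src_in_b]
    W = translation.weights[src_idx]  # n_src_used x n_target

    tgt_in_a = [i for i, g in enumerate(translation.target_genes)
                if g in pm_a.var_names]
    reachable = np.asarray(W[:, tgt_in_a].sum(axis=0)).ravel() > 0
    tgt_cols = [tgt_in_a[i] for i in np.flatnonzero(reachable)]
    shared_genes = [translation.target_genes[i] for i in tgt_cols]
    if not shared_genes:
        raise ValueError("empty translation: no target genes reachable")

    Xb_src = _dense(pm_b[:, src_in_b].X)
    Xb_t = Xb_src @ W[:, tgt_cols].toarray()
    Xa = _dense(pm_a[:, shared_genes].X)

    Za = _zscore_cols(Xa)
    Zb = _zscore_cols(Xb_t)

    n_pcs = min(n_joint_pcs, Za.shape[0] + Zb.shape[0] - 1, Za.shape[1])
    if n_pcs >= 1:
        from sklearn.decomposition import PCA
        pca = PCA(n_components=n_pcs, svd_solver="randomized",
                  random_state=0)
        Y = pca.fit_transform(np.vstack([Za, Zb]))
        Ya, Yb = Y[:Za.shape[0]], Y[Za.shape[0]:]
    else:
        Ya, Yb = Za, Zb

    nn_b = NearestNeighbors(n_neighbors=k_cross, algorithm="brute").fit(Yb)
    dist_ab, nbrs_ab = nn_b.kneighbors(Ya)
    nn_a = NearestNeighbors(n_neighbors=k_cross, algorithm="brute").fit(Ya)
    dist_ba, nbrs_ba = nn_a.kneighbors(Yb)

    return JointMap(adata_a=pm_a, adata_b=pm_b, shared_genes=shared_genes,
                    translation=translation,
                    homology=homology if homology is not None else pd.DataFrame(
                        columns=["gene_a", "gene_b", "bitscore"]),
                    nbrs_ab=nbrs_ab, dist_ab=dist_ab,
                    nbrs_ba=nbrs_ba, dist_ba=dist_ba)


def alignment_scores(jm: JointMap, labels_a, labels_b
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster-pair alignment score matrix and best-match pairing.

    ``score(i, j)`` is the average of (a) the mean, over cells of species-A
    cluster *i*, of the fraction of their cross-neighbors lying in species-B
    cluster *j*, and (b) the symmetric species-B term. All entries lie in
    [0, 1]; 1 means the two clusters exhaust each other's cross-neighbors.
    The second return value is the per-cluster argmax pairing from both
    sides (the Sankey edges).
    """
    labels_a = np.asarray(labels_a).astype(str)
    labels_b = np.asarray(labels_b).astype(str)
    if len(labels_a) != jm.adata_a.n_obs or len(labels_b) != jm.adata_b.n_obs:
        raise ValueError("cluster label vectors do not match cell counts")
    cl_a = sorted(pd.unique(labels_a))
    cl_b = sorted(pd.unique(labels_b))
    ia = {c: i for i, c in enumerate(cl_a)}
    ib = {c: i for i, c in enumerate(cl_b)}
    code_a = np.array([ia[c] for c in labels_a])
    code_b = np.array([ib[c] for c in labels_b])

    # per-cell cross-neighbor cluster fractions
    k = jm.nbrs_ab.shape[1]
    frac_ab = np.zeros((jm.adata_a.n_obs, len(cl_b)))
    nb_codes = code_b[jm.nbrs_ab]
    for j in range(len(cl_b)):
        frac_ab[:, j] = (nb_codes == j).mean(axis=1)
    frac_ba = np.zeros((jm.adata_b.n_obs, len(cl_a)))
    na_codes = code_a[jm.nbrs_ba]
    for i in range(len(cl_a)):
        frac_ba[:, i] = (na_codes == i).mean(axis=1)

    M1 = np.vstack([frac_ab[code_a == i].mean(axis=0) for i in
                    range(len(cl_a))])
    M2 = np.vstack([frac_ba[code_b == j].mean(axis=0) for j in
                    range(len(cl_b))])
    score = 0.5 * (M1 + M2.T)
    mat = pd.DataFrame(score, index=pd.Index(cl_a, name="cluster_a"),
                       columns=pd.Index(cl_b, name="cluster_b"))

    pairs = []
    for c in cl_a:
        j = mat.loc[c].idxmax()
        pairs.append(("a", c, j, mat.loc[c, j]))
    for c in cl_b:
        i = mat[c].idxmax()
        pairs.append(("b", c, i, mat.loc[i, c]))
    best = pd.DataFrame(pairs, columns=["side", "cluster", "best_match",
                                        "score"])
    return mat, best


def smooth_expression(adata: ad.AnnData, genes=None) -> np.ndarray:
    """Neighborhood-mean smoothing over the within-species kNN graph.

    Each cell's value is replaced by the unweighted mean over itself and its
    graph neighbors: ``(D + I)^-1 (A + I) x`` with ``A`` the binary
    adjacency. Returns a dense cells x genes array.
    """
    X = _dense(adata.X if genes is None else adata[:, genes].X)
    g = adata.obsp["distances"]
    A = (g != 0).astype(float)
    A = A + sp.eye(A.shape[0], format="csr")
    deg = np.asarray(A.sum(axis=1)).ravel()
    P = sp.diags(1.0 / deg) @ A
    return np.asarray(P @ X)


def _impute_cross(adata_from: ad.AnnData, nbrs: np.ndarray,
                  genes) -> np.ndarray:
    """Mean expression over each target cell's cross-species neighbors."""
    X = _dense(adata_from[:, genes].X)
    return X[nbrs].mean(axis=1)


def _corr_columns(U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix between columns of U and columns of V.

    Constant columns yield NaN (flagged, never silently zero).
    """
    Uc = U - U.mean(axis=0)
    Vc = V - V.mean(axis=0)
    un = np.linalg.norm(Uc, axis=0)
    vn = np.linalg.norm(Vc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = (Uc.T @ Vc) / np.outer(un, vn)
    C[:, vn == 0] = np.nan
    C[un == 0, :] = np.nan
    return C


def pair_correlations(jm: JointMap, genes_a: list, genes_b: list
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Directional correlation matrices for gene sets of both species.

    Returns ``(C_a, C_b)``, each ``len(genes_a) x len(genes_b)``: ``C_a`` is
    computed on species-A cells (smoothed A expression vs cross-imputed B
    expression) and ``C_b`` on species-B cells.
    """
    SA = smooth_expression(jm.adata_a, genes_a)
    IB = _impute_cross(jm.adata_b, jm.nbrs_ab, genes_b)
    C_a = _corr_columns(SA, IB)

    SB = smooth_expression(jm.adata_b, genes_b)
    IA = _impute_cross(jm.adata_a, jm.nbrs_ba, genes_a)
    C_b = _corr_columns(IA, SB)
    return C_a, C_b


def gene_pair_correlation(jm: JointMap, gene_a: str, gene_b: str
                          ) -> float | None:
    """Symmetric cross-species expression correlation of one gene pair.

    Average of both directional Pearson correlations (A cells: smoothed
    ``gene_a`` vs imputed ``gene_b``; B cells: the mirror). Returns ``None``
    when either side is constant (correlation undefined).
    """
    if gene_a not in jm.adata_a.var_names:
        raise KeyError(f"{gene_a!r} not in species-A genes")
    if gene_b not in jm.adata_b.var_names:
        raise KeyError(f"{gene_b!r} not in species-B genes")
    C_a, C_b = pair_correlations(jm, [gene_a], [gene_b])
    sym = 0.5 * (C_a[0, 0] + C_b[0, 0])
    return None if np.isnan(sym) else float(sym)


def _bitscore_lookup(homology: pd.DataFrame) -> dict:
    return {(r.gene_a, r.gene_b): r.bitscore
            for r in homology.itertuples(index=False)}


def find_gene_pairs(jm: JointMap, min_corr: float = 0.2,
                    n_top_var: int = 100,
                    candidates: list[tuple[str, str]] | None = None
                    ) -> pd.DataFrame:
    """Cross-species gene pairs passing a symmetric-correlation floor.

    The candidate universe is the homology table plus the cross product of
    the ``n_top_var`` most variable genes of each species (by variance of
    log-normalized expression), unless an explicit candidate list is given.
    Pairs whose symmetric correlation is strictly greater than ``min_corr``
    are returned, annotated with bitscore and inverse bitscore (+inf when
    the pair has no homology record).
    """
    if candidates is None:
        cand = {(r.gene_a, r.gene_b) for r in
                jm.homology.itertuples(index=False)
                if r.gene_a in jm.adata_a.var_names
                and r.gene_b in jm.adata_b.var_names}

        def _top_var(adata):
            v = pd.Series(_dense(adata.X).var(axis=0),
                          index=adata.var_names)
            return v.sort_values(ascending=False, kind="stable"
                                 ).index[:n_top_var]

        cand |= {(ga, gb) for ga in _top_var(jm.adata_a)
                 for gb in _top_var(jm.adata_b)}
        candidates = sorted(cand)

    genes_a = sorted({p[0] for p in candidates})
    genes_b = sorted({p[1] for p in candidates})
    ia = {g: i for i, g in enumerate(genes_a)}
    ib = {g: i for i, g in enumerate(genes_b)}
    C_a, C_b = pair_correlations(jm, genes_a, genes_b)
    sym = 0.5 * (C_a + C_b)

    bits = _bitscore_lookup(jm.homology)
    rows = []
    for ga, gb in candidates:
        c = sym[ia[ga], ib[gb]]
        if np.isnan(c) or not c > min_corr:
            continue
        bs = bits.get((ga, gb))
        rows.append((ga, gb, float(c),
                     float(bs) if bs is not None else np.nan,
                     1.0 / bs if bs is not None else np.inf))
    out = pd.DataFrame(rows, columns=["gene_a", "gene_b", "correlation",
                                      "bitscore", "inverse_bitscore"])
    return out.sort_values(["correlation", "gene_a", "gene_b"],
                           ascending=[False, True, True],
                           ignore_index=True)
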