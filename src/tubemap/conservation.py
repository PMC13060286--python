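"""Tri-partite conservation reference and functional-category scores.

For each epithelial cell state the top distinguishing markers of both
species are paired through the homology table (one-to-many hits resolve to
the highest-bitscore partner) and scored with the cross-species gene-pair
correlation. Markers whose ortholog pair clears the correlation floor are
*conserved*; markers without an ortholog, or whose ortholog pair does not
clear it, are *species-specific*. The three lists per state are disjoint on
genes.

Category scores generalize ortholog-group (KOG-style) profiling: any
user-supplied gene -> category map is averaged over the per-state z-scored
mean expression of its member genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from . import mapping

logger = logging.getLogger(__name__)


def top_state_markers(marker_table: pd.DataFrame, n_top: int = 25
                      ) -> dict[str, list[str]]:
    """Top ``n_top`` positive markers per state from a Wilcoxon marker table.

    Ordered by ascending adjusted p, then descending log fold change, then
    gene id; only genes with positive fold change qualify. States with fewer
    than ``n_top`` qualifying genes return all of them with a warning. The
    lists are prefix-stable: the top-5 list is a prefix of the top-10 list.
    """
    out: dict[str, list[str]] = {}
    for state, sub in marker_table.groupby("cluster", observed=True):
        pos = sub[sub["log_fold_change"] > 0]
        ranked = pos.sort_values(
            ["adjusted_p", "log_fold_change", "gene"],
            ascending=[True, False, True])
        genes = ranked["gene"].tolist()
        if len(genes) < n_top:
            logger.warning("state %s has only %d qualifying markers "
                           "(requested %d)", state, len(genes), n_top)
        out[str(state)] = genes[:n_top]
    return out


@dataclass
class ConservationReference:
    """Per-state conserved / A-specific / B-specific marker lists."""

    conserved: dict = field(default_factory=dict)   # state -> [(ga, gb, corr)]
    a_specific: dict = field(default_factory=dict)  # state -> [(ga, corr|None)]
    b_specific: dict = field(default_factory=dict)  # state -> [(gb, corr|None)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for st in sorted(self.conserved):
            for ga, gb, c in self.conserved[st]:
                rows.append((st, "conserved", ga, gb, c))
            for ga, c in self.a_specific.get(st, []):
                rows.append((st, "a_specific", ga, "", c))
            for gb, c in self.b_specific.get(st, []):
                rows.append((st, "b_specific", "", gb, c))
        return pd.DataFrame(rows, columns=["state", "class", "gene_a",
                                           "gene_b", "correlation"])


def _best_partner(homology: pd.DataFrame, source: str) -> dict[str, str]:
    """Highest-bitscore ortholog partner for every gene of one species."""
    src, tgt = ("gene_a", "gene_b") if source == "a" else ("gene_b", "gene_a")
    best = (homology.sort_values([src, "bitscore", tgt])
                    .groupby(src, sort=True).last())
    return best[tgt].to_dict()


def classify_conservation(state_markers_a: dict, state_markers_b: dict,
                          homology: pd.DataFrame, jm: mapping.JointMap,
                          threshold: float = 0.2) -> ConservationReference:
    """Split per-state markers into conserved and species-specific lists.

    A marker whose best-bitscore ortholog pair has symmetric cross-species
    correlation strictly above ``threshold`` is conserved (reported with the
    correlation, sorted descending). A marker with no ortholog, or whose
    ortholog pair does not clear the threshold, is species-specific (sorted
    ascending by correlation, missing correlations first). Swapping the two
    species swaps the A- and B-specific lists exactly.
    """
    best_ab = _best_partner(homology, "a")
    best_ba = _best_partner(homology, "b")
    states = sorted(set(state_markers_a) | set(state_markers_b))

    # gather every pair needing a correlation, compute in one shot
    pairs = []
    for st in states:
        for ga in state_markers_a.get(st, []):
            gb = best_ab.get(ga)
            if gb is not None and gb in jm.adata_b.var_names \
                    and ga in jm.adata_a.var_names:
                pairs.append((ga, gb))
        for gb in state_markers_b.get(st, []):
            ga = best_ba.get(gb)
            if ga is not None and ga in jm.adata_a.var_names \
                    and gb in jm.adata_b.var_names:
                pairs.append((ga, gb))
    corr: dict[tuple[str, str], float | None] = {}
    if pairs:
        genes_a = sorted({p[0] for p in pairs})
        genes_b = sorted({p[1] for p in pairs})
        ia = {g: i for i, g in enumerate(genes_a)}
        ib = {g: i for i, g in enumerate(genes_b)}
        C_a, C_b = mapping.pair_correlations(jm, genes_a, genes_b)
        sym = 0.5 * (C_a + C_b)
        for ga, gb in set(pairs):
            v = sym[ia[ga], ib[gb]]
            corr[(ga, gb)] = None if np.isnan(v) else float(v)

    ref = ConservationReference()
    for st in states:
        conserved: dict[tuple[str, str], float] = {}
        a_rest: list[tuple[str, float | None]] = []
        b_rest: list[tuple[str, float | None]] = []
        for ga in state_markers_a.get(st, []):
            gb = best_ab.get(ga)
            c = corr.get((ga, gb)) if gb is not None else None
            if c is not None and c > threshold:
                conserved[(ga, gb)] = c
            else:
                a_rest.append((ga, c))
        for gb in state_markers_b.get(st, []):
            ga = best_ba.get(gb)
            c = corr.get((ga, gb)) if ga is not None else None
            if c is not None and c > threshold:
                conserved.setdefault((ga, gb), c)
            else:
                b_rest.append((gb, c))
        # disjointness: a gene conserved through either species leaves the
        # specific lists
        cons_genes = {g for p in conserved for g in p}
        a_rest = [(g, c) for g, c in a_rest if g not in cons_genes]
        b_rest = [(g, c) for g, c in b_rest if g not in cons_genes]

        key_missing_first = lambda gc: (gc[1] is not None,
                                        gc[1] if gc[1] is not None else 0.0,
                                        gc[0])
        ref.conserved[st] = sorted(
            [(ga, gb, c) for (ga, gb), c in conserved.items()],
            key=lambda r: (-r[2], r[0], r[1]))
        ref.a_specific[st] = sorted(a_rest, key=key_missing_first)
        ref.b_specific[st] = sorted(b_rest, key=key_missing_first)
    return ref


def category_scores(adata: ad.AnnData, state_labels,
                    gene_to_category: pd.DataFrame) -> pd.DataFrame:
    """State x category scores from a user-supplied gene -> category map.

    Each gene's mean expression per state is z-scored across states (so a
    gene's contribution row has mean 0); the category score is the mean over
    its member genes expressed in the data. Categories with no expressed
    member gene are dropped with a warning.
    """
    states = np.asarray(state_labels).astype(str)
    X = adata.X
    X = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)
    uniq = sorted(pd.unique(states))
    means = np.vstack([X[states == s].mean(axis=0) for s in uniq])
    mu = means.mean(axis=0)
    sd = means.std(axis=0)
    Z = np.where(sd > 0, (means - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    zdf = pd.DataFrame(Z, index=uniq, columns=adata.var_names)

    scores = {}
    for cat, sub in gene_to_category.groupby("category"):
        genes = [g for g in sub["gene"] if g in adata.var_names]
        genes = [g for g in genes if X[:, adata.var_names.get_loc(g)].std() > 0]
        if not genes:
            logger.warning("category %r has no expressed genes; dropped", cat)
            continue
        scores[cat] = zdf[genes].mean(axis=1)
    out = pd.DataFrame(scores)
    out.index.name = "state"
    return out
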