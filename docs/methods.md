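# Methods

This note documents the models and procedures `tubemap` implements, the
design choices that were genuinely open, and what the synthetic benchmark
does and does not demonstrate.

## Quality control and preprocessing

A cell is removed when its mitochondrial fraction exceeds the cap
(0.30 for the mouse-like species A, 0.20 for the human-like species B;
count and feature floors of 750 / 200 are shared), when its total counts
fall below the count floor, or when its detected genes fall below the
feature floor. All three inequalities are **strict** ("greater than" /
"fewer than"), so a cell at exactly the boundary is kept; filtering is
therefore monotone in every threshold. Mitochondrial genes are identified
by a configurable name-prefix rule (defaults `mt-`, `MT-`) because no
universal annotation exists in plain count matrices.

Normalization is counts-per-10^4 followed by log1p. Highly variable genes
are flagged by mean-binned standardized dispersion (variance/mean of
log-expression, z-scored within 20 equal-frequency mean bins), ties broken
lexicographically; the expression matrix is z-scored per gene before PCA.
"95% of the total variance" is read as 95% of the variance captured by the
computed components (at most 100): a full-rank decomposition at atlas scale
is impractical and the leading components carry the structure the
downstream graph needs. The kNN graph takes each cell's k = 70 Euclidean
neighbors in PC space and symmetrizes by edge union, keeping Euclidean
weights. Clustering is Leiden on that graph (RB-configuration modularity,
resolution 0.7, fixed seed), labels ordered by descending cluster size for
cross-run comparability.

Marker detection is a vectorized one-vs-rest Wilcoxon rank-sum test with
tie-corrected normal approximation and no continuity correction (matching
the exhaustive-enumeration oracle exactly on the U statistic), log2 fold
change of expm1-means with a 1e-9 pseudocount, and Benjamini–Hochberg
adjustment within each cluster's gene family — the multiple-testing scope
is per one-vs-rest family, a choice the underlying procedure leaves open.

## Cross-species mapping

The full iterative manifold-alignment algorithm used by atlas studies
(alternating gene-weight and cell-graph refinement) is deliberately **not**
reproduced; `tubemap` implements a single-round, homology-seeded
simplification whose outputs carry the same semantics (cluster alignment
scores, cross-species gene-pair correlations) without promising numeric
equality with any external tool.

Gene translation: from best-hit BLAST records, each source gene
distributes weight over its hits proportionally to bitscore (weights sum
to 1). Species-B log-expression is pushed through the translation into
species-A gene space; shared dimensions are z-scored per species (a crude
but deterministic species-effect removal); the stacked matrix is reduced
to 100 principal components before the cross-species neighbor search.
That joint reduction is essential, not cosmetic: in the raw z-scored gene
space most dimensions are noise, cross-neighbors inside a homogeneous cell
population are selected nearly at random, and the imputed expression
profiles lose all curve-shape information — every progenitor-active pair
then correlates equally. Reducing to the leading joint components is the
standard denoising step of integration pipelines and restores partner
discrimination.

The alignment score of clusters (i, j) averages two means of
cross-neighbor membership fractions and lies in [0, 1]; 1 means the two
clusters exhaust each other's cross-neighborhoods. Gene-pair correlations
smooth the within-species profile over the kNN graph (mean over self and
neighbors), impute the partner gene as the unweighted mean over
cross-neighbors (distance weighting was rejected for determinism and
simplicity), take the Pearson correlation, and average both directions.
Constant profiles return a flagged null, never a silent zero. The
candidate universe for pair finding is the homology table plus the cross
product of each species' `n_candidate_genes = 500` most variable genes by
log-expression variance; the cap exists purely to bound compute and is
deliberately generous — binned-dispersion ranking was rejected here
because it under-ranks moderately expressed program genes.

## Trajectory

Pseudotime is the shortest-path (Dijkstra) distance from a root cell along
the distance-weighted kNN graph — a documented substitution for
learned-graph trajectory inference; accuracy is judged by rank agreement
with latent truth, not coordinate equality. The root is the medoid of the
progenitor cluster. Secretory cells take negative sign, ciliogenic
(pre-ciliated + ciliated) positive, anchoring progenitors near 0;
progenitor cells inherit the sign of their graph-nearest non-progenitor
cell (ties toward secretory for determinism), and each sign group is
rescaled to max 1.

"Equally sized bins" is read as equal **cell count** (robust to density
variation along the trajectory), 40 bins spanning the whole signed axis
jointly. Cells sort by signed pseudotime with cell-id tie-breaks and are
cut into contiguous groups differing by at most one cell. Trends z-score
each gene over the analyzed subset (z-scoring follows subsetting; constant
genes give zero rows) and average within bins, so the cell-weighted trend
mean is 0 by construction.

Signature scoring is the rank-based Mann–Whitney statistic: per cell,
genes rank by descending expression with average ties, ranks cap at
`r_max = 1500` (the published default of the rank-capped scoring method),
and the score is `1 - U'/(n_s * r_max)` in [0, 1].

## Conservation reference and category scores

Per state, the top 25 positive-fold-change markers (adjusted p ascending,
fold change descending, gene id) of each species are paired through their
highest-bitscore ortholog and scored with the symmetric gene-pair
correlation. Pairs above the 0.2 correlation floor — the only correlation
floor the homologous-pair alignment states; the conserved/specific cut is
not otherwise specified and is configurable — are *conserved*; markers
without an ortholog or below the floor are *species-specific* (sorted
ascending, missing correlations first). The three per-state lists are
disjoint on genes and swapping species swaps the two specific lists
exactly. Category scores generalize ortholog-group profiling: per-state
mean expression, z-scored per gene across states, averaged over each
user-supplied category's expressed genes.

## Analog discovery

Inverse BLAST score is the reciprocal bitscore; a pair without any
homology record gets +inf (serialized "inf"), encoding "no detectable
sequence similarity" — it passes the > 0.010 filter by design, whereas
every true ortholog (bitscore >= 120 in the generator) fails it.
Bitscore, not e-value, is inverted because it is length- and
database-independent. Candidates must have the human-side gene in the
surface-marker set, symmetric correlation > 0.4 (the symmetric rather than
directional value — a choice the procedure leaves open) and inverse score
> 0.010; all boundaries are strict. Progenitor specificity is the fold
change of mean log-normalized expression in progenitor-majority bins over
all other bins (ε = 1e-4); bins are labeled by majority vote of cell-state
labels, which may come from cluster annotation or, in synthetic runs, the
planted truth. Before ranking, candidates collapse to one row per surface
gene keeping the best-correlated partner — the surface gene is the
experimental deliverable, and without the collapse every pair sharing a
surface gene ties on fold change and floods the list. The ranked top 10 is
the output; the final pick among them is a human judgment and out of
scope.

## Synthetic data generator

The generator emulates two species sharing the bipotent-progenitor lineage:
each cell has a branch (secretory or ciliogenic) and a latent time t in
[0, 1]; states follow fixed windows (progenitor t <= 0.25; secretory
beyond; pre-ciliated 0.25–0.625 and ciliated beyond on the ciliogenic
branch). Latent time is drawn from state-centered Gaussian mixtures with a
~20% uniform bridge: differentiating epithelia accumulate cells in
metastable states with comparatively few cells in transit, which is also
what makes the states recoverable as clusters at the fixed resolution.

Gene programs are logistic activations over t, branch-restricted where
appropriate. A structural rule worth stating: **no branch-restricted
program is active at t = 0** — a bipotent progenitor carries no expression
evidence of its future branch, so decaying branch programs switch on at
the branch point (bump curves). Consequences: (i) the per-cell latent
branch of an early progenitor is unidentifiable from expression, so
branch-sign accuracy is evaluated on non-progenitor cells; (ii) early in
development of the generator, branch-restricted "fall" programs violated
this rule and artificially split the progenitor pool by branch.

Per species and state there are 10 strong conserved markers (ortholog
pairs sharing program parameters exactly), 10 species-specific markers
(program in exactly one species, no ortholog), and 30 weaker identity
genes; 40 shared trunk-gradient genes (decays with midpoints 0.02–0.70)
and 40 per-branch gradient genes (rises, midpoints 0.35–0.95) give the
manifold continuous time-resolution — dense enough that cross-species
neighbors resolve latent time inside the progenitor window. Planted
markers get 10x reduced baselines (markers are near-silent off-state;
without this their fold changes do not dominate the weaker identity
genes). 10% of orthologs are "divergent" with independent programs per
species, exercising the species-specific classifier. A ciliogenic
handoff pair (early bump decaying as a late riser grows) reproduces the
early-to-late program transition; its trend curves cross exactly once
along the expressed (pre-ciliated/ciliated-majority) bins — the crossing
statistic is restricted to those bins because in bins where both genes are
off the trend difference is pure noise.

The 5 analog pairs share progenitor-dominant bump programs (pair-specific
centers) plus a weak pair-specific secondary feature elsewhere on the
trajectory, in both species, with **no homology record**. The secondary
feature reflects that real analogous markers are not pure state
indicators, and it is what keeps the true partner the best-correlated one
after neighborhood averaging; with pure progenitor-window curves all
progenitor genes tie within ~0.003 correlation. Analog surface flags sit
on the species-B analogs plus decoys (secretory/ciliated conserved-marker
genes and random baseline genes) that exercise the fold-change ranking:
decoys pass the correlation and inverse-BLAST filters but rank below the
analogs because their progenitor fold change is below 1.

Counts are Gamma–Poisson (negative binomial, dispersion 0.3 — a moderate
droplet-data regime) with mean library × relative intensity; library sizes
are log-normal with median 5000 (sigma 0.3). Ortholog bitscores are
log-normal (median 200, sigma 0.25) floored at 120 so every true ortholog
has inverse score < 0.010. Planted low-quality cells (5%) get libraries
near 350 (clipped below the 750 floor) and 40–60% mitochondrial intensity,
violating every preset's QC. Baseline mitochondrial mass is 3%.

### What the benchmark does not show

The generator omits ambient RNA, doublets, and batch effects (their
removal/correction is outside this pipeline's scope), uses one-to-one
orthologs only (no paralog expansions), exactly two branches, and
species differences limited to divergent programs — there is no global
species shift beyond what per-species z-scoring removes. Passing tests
demonstrate that the implemented procedures recover the structure they
assume, at desk scale, under this noise model; they do not certify
performance on real atlases, where the alignment step in particular is a
simplification of iterative manifold alignment.

## Problem sizes and determinism

Default synthetic conditions: 3000 cells per species, 1500/1800 genes,
1000 orthologs, 5 analog pairs, seed 0; the full pipeline runs in about a
minute on one CPU, and the test suite uses a 400-cell configuration for
everything that does not need the default scale. All randomness flows from
the single config seed (generator, PCA solver, community detection); the
joint-PCA solver seed is fixed at 0. CLI outputs are byte-reproducible for
a fixed seed. Degenerate inputs fail loudly: all-cells-removed QC,
zero-total cells, disconnected trajectory graphs (component sizes
reported), missing branch-map entries, empty translations, constant
correlation inputs, and empty signature sets are all explicit errors or
flagged nulls rather than silent results.
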