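"""End-to-end orchestration of the cross-species analysis.

Wires the modules together in the order a study would run them: simulate
(or load) two species' counts -> per-species QC / normalization / HVG / PCA
/ kNN / clustering / markers -> homology-weighted joint map with alignment
scores and gene-pair correlations -> per-species signed pseudotime with
40-bin trends -> conservation reference -> analog candidate ranking. The
CLI and the acceptance script are thin wrappers over these functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from . import analogs as analogs_mod
from . import conservation, mapping, preprocess, simulate, trajectory
from .config import PipelineConfig

logger = logging.getLogger(__name__)

#: species preset applied to each side (A is mouse-like, B human-like)
SPECIES_PRESET = {"a": "mouse", "b": "human"}


@dataclass
class PipelineResult:
    config: PipelineConfig
    truth: simulate.SyntheticTruth | None
    adatas: dict                      # species -> processed AnnData
    qc_reports: dict
    markers: dict                     # species -> cluster MarkerTable
    state_markers: dict               # species -> state -> gene list
    cluster_states: dict              # species -> {cluster -> state}
    jm: mapping.JointMap | None = None
    alignment: pd.DataFrame | None = None
    alignment_pairs: pd.DataFrame | None = None
    gene_pairs: pd.DataFrame | None = None
    trajectories: dict = field(default_factory=dict)
    conservation_ref: conservation.ConservationReference | None = None
    candidates: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


def process_species(adata: ad.AnnData, config: PipelineConfig,
                    preset: str | None = None, seed: int | None = None
                    ) -> tuple[ad.AnnData, dict]:
    """QC through clustering for one species' count matrix."""
    seed = config.seed if seed is None else seed
    thr = config.qc_thresholds(preset)
    adata, report = preprocess.qc_filter(adata, **thr)
    preprocess.normalize_log(adata, scale=config.scale)
    preprocess.select_hvg(adata, n_hvg=config.n_hvg)
    preprocess.embed_pca(adata, variance_target=config.variance_target,
                         max_components=config.max_components, seed=seed)
    preprocess.build_knn(adata, k=min(config.knn_k, adata.n_obs - 1))
    preprocess.cluster(adata, resolution=config.cluster_resolution, seed=seed)
    return adata, report


def state_labels_from_clusters(adata: ad.AnnData,
                               truth_states=None) -> np.ndarray:
    """Per-cell state labels via majority-vote cluster annotation.

    With synthetic truth available the vote uses the planted states (the
    stand-in for canonical-marker annotation of a real atlas); otherwise
    ``obs["state"]`` must already exist.
    """
    if truth_states is None:
        if "state" in adata.obs.columns:
            return adata.obs["state"].to_numpy()
        raise ValueError("no truth states and no obs['state'] annotation")
    mapping_ = preprocess.annotate_clusters(adata.obs["cluster"], truth_states)
    states = np.array([mapping_[c] for c in
                       adata.obs["cluster"].astype(str)], dtype=object)
    adata.obs["state"] = states
    return states


def run_pipeline(config: PipelineConfig, seed: int | None = None
                 ) -> PipelineResult:
    """Full synthetic-data run: generate, process, map, trace, classify."""
    seed = config.seed if seed is None else seed
    truth = simulate.generate_truth(config.synthetic, seed)
    adata_a, adata_b = simulate.simulate_counts(truth, config.synthetic,
                                                seed + 1)
    return run_from_counts(adata_a, adata_b, truth.orthologs, config,
                           seed=seed, truth=truth,
                           surface_genes=truth.surface_genes_b)


def run_from_counts(adata_a: ad.AnnData, adata_b: ad.AnnData,
                    homology: pd.DataFrame, config: PipelineConfig,
                    seed: int | None = None,
                    truth: simulate.SyntheticTruth | None = None,
                    surface_genes=None) -> PipelineResult:
    seed = config.seed if seed is None else seed
    adatas, reports, markers, state_markers, cluster_states = {}, {}, {}, {}, {}
    for sp_, raw in (("a", adata_a), ("b", adata_b)):
        pm, report = process_species(raw, config,
                                     preset=SPECIES_PRESET[sp_], seed=seed)
        states = state_labels_from_clusters(
            pm, pm.obs["true_state"].to_numpy()
            if "true_state" in pm.obs.columns else None)
        markers[sp_] = preprocess.rank_markers_wilcoxon(pm, labels=states)
        state_markers[sp_] = conservation.top_state_markers(
            markers[sp_], n_top=config.n_top_markers)
        cluster_states[sp_] = preprocess.annotate_clusters(
            pm.obs["cluster"], states)
        adatas[sp_], reports[sp_] = pm, report

    res = PipelineResult(config=config, truth=truth, adatas=adatas,
                         qc_reports=reports, markers=markers,
                         state_markers=state_markers,
                         cluster_states=cluster_states)

    # cross-species map
    translation = mapping.build_gene_translation(homology, source="b")
    res.jm = mapping.joint_embed(adatas["a"], adatas["b"], translation,
                                 k_cross=config.k_cross, homology=homology)
    res.alignment, res.alignment_pairs = mapping.alignment_scores(
        res.jm, adatas["a"].obs["state"], adatas["b"].obs["state"])
    res.gene_pairs = mapping.find_gene_pairs(
        res.jm, min_corr=config.conservation_corr_min,
        n_top_var=config.n_candidate_genes)

    # per-species trajectories
    for sp_ in ("a", "b"):
        res.trajectories[sp_] = trajectory.run_trajectory(
            adatas[sp_], adatas[sp_].obs["state"], n_bins=config.n_bins)

    # conservation reference
    res.conservation_ref = conservation.classify_conservation(
        state_markers["a"], state_markers["b"], homology, res.jm,
        threshold=config.conservation_corr_min)

    # analog discovery (surface annotation on the human-like species B)
    if surface_genes is None and "is_surface" in adatas["b"].var.columns:
        surface_genes = adatas["b"].var_names[
            adatas["b"].var["is_surface"].astype(bool)].tolist()
    if surface_genes is not None:
        analog_pairs = mapping.find_gene_pairs(
            res.jm, min_corr=config.analog_corr_min,
            n_top_var=config.n_candidate_genes)
        cand = analogs_mod.filter_analog_candidates(
            analog_pairs, surface_genes,
            analog_corr_min=config.analog_corr_min,
            inv_bitscore_min=config.inv_bitscore_min)
        traj_b = res.trajectories["b"]
        maj = traj_b.bin_table.set_index("bin")["majority_state"]
        spec = analogs_mod.progenitor_specificity(
            adatas["b"], traj_b.cells["bin"].to_numpy(), maj)
        res.candidates = analogs_mod.rank_candidates(cand, spec,
                                                     top_k=config.top_k)
        res.extras["analog_pairs_filtered"] = cand
    return res
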