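"""Seeded two-species synthetic dataset with planted ground truth.

The generator emulates the tubal-epithelium lineage the pipeline is built
for: in both species every cell sits on one of two differentiation branches
leaving a bipotent progenitor pool — *progenitor -> secretory* or
*progenitor -> pre-ciliated -> ciliated* — parameterized by a latent time
``t`` in [0, 1]. Gene programs are logistic activation curves over ``t``
with branch-restricted modules:

* planted **conserved markers** (10 per state by default) are one-to-one
  orthologs sharing program parameters exactly across species;
* planted **species-specific markers** carry a state program in exactly one
  species and have no ortholog;
* planted **analogous pairs** share a progenitor-restricted program in both
  species but have *no homology record at all* (their inverse BLAST score is
  infinite) — the ground truth for the analog-discovery stage; each pair has
  its own activation curve so the matched partner is the best-correlated one;
* a **program-handoff pair** on the ciliogenic branch (an early gene
  decaying as a late gene rises) exercises the trend-crossing analysis;
* weaker identity modules and monotone gradient genes give each state a
  recoverable cluster and each branch a continuous manifold.

Counts are negative-binomial (Gamma–Poisson) with configurable dispersion;
library sizes are log-normal. A configurable fraction of cells is planted
as low quality (library below the count floor, mitochondrial fraction above
every preset cap) to exercise QC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import SyntheticConfig
from . import io as tio

STATES = ("progenitor", "secretory", "pre-ciliated", "ciliated")
BRANCH_SECRETORY = "secretory"
BRANCH_CILIOGENIC = "ciliogenic"
LOW_QUALITY = "low_quality"

#: state boundaries on latent time
T_PROGENITOR_MAX = 0.25
T_CILIATED_MIN = 0.625

STATE_CATEGORY = {
    "progenitor": "signal_transduction",
    "secretory": "secretion_transport",
    "pre-ciliated": "cytoskeleton_assembly",
    "ciliated": "energy_production",
}


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _activation(kind: str, params: tuple, t: np.ndarray) -> np.ndarray:
    if kind == "rise":
        m, s = params
        return _sigmoid((t - m) / s)
    if kind == "fall":
        m, s = params
        return _sigmoid((m - t) / s)
    if kind == "bump":
        m1, s1, m2, s2 = params
        return _sigmoid((t - m1) / s1) * _sigmoid((m2 - t) / s2)
    raise ValueError(f"unknown activation kind {kind!r}")


#: canonical state programs (branch restriction, activation kind, parameters)
STATE_PROGRAM = {
    "progenitor": (None, "fall", (0.22, 0.04)),
    "secretory": (BRANCH_SECRETORY, "rise", (0.30, 0.05)),
    "pre-ciliated": (BRANCH_CILIOGENIC, "bump", (0.28, 0.04, 0.62, 0.04)),
    "ciliated": (BRANCH_CILIOGENIC, "rise", (0.60, 0.04)),
}


def state_from_latent(branch: str, t: float) -> str:
    """Map a (branch, latent time) coordinate to its cell state."""
    if t <= T_PROGENITOR_MAX:
        return "progenitor"
    if branch == BRANCH_SECRETORY:
        return "secretory"
    return "pre-ciliated" if t <= T_CILIATED_MIN else "ciliated"


@dataclass
class SyntheticTruth:
    """Machine-readable ground truth of one generated two-species dataset."""

    config: SyntheticConfig
    cells: dict            # species -> DataFrame(cell_id, state, branch, t, low_quality, region)
    genes: dict            # species -> DataFrame(gene_id, role, state, is_mito, is_surface)
    programs: dict         # species -> {gene index -> [(branch, kind, params, amplitude)]}
    baselines: dict        # species -> ndarray of per-gene baseline intensity
    orthologs: pd.DataFrame  # gene_a, gene_b, pident, evalue, bitscore, divergent
    conserved_markers: dict  # state -> [(gene_a, gene_b)]
    a_specific_markers: dict  # state -> [gene_a]
    b_specific_markers: dict  # state -> [gene_b]
    analog_pairs: list     # [(gene_a, gene_b)]
    handoff_pair: dict     # species -> (early gene, late gene)
    surface_genes_b: list = field(default_factory=list)

    def low_quality_cells(self, species: str) -> list[str]:
        df = self.cells[species]
        return df.loc[df["low_quality"], "cell_id"].tolist()

    def to_json(self) -> str:
        """Serialize the public truth record (sorted keys, stable floats)."""
        rec = {
            "cells": {sp_: df.to_dict(orient="list")
                      for sp_, df in sorted(self.cells.items())},
            "orthologs": self.orthologs.to_dict(orient="list"),
            "conserved_markers": {s: [list(p) for p in v]
                                  for s, v in self.conserved_markers.items()},
            "a_specific_markers": self.a_specific_markers,
            "b_specific_markers": self.b_specific_markers,
            "analog_pairs": [list(p) for p in self.analog_pairs],
            "handoff_pair": {k: list(v) for k, v in self.handoff_pair.items()},
            "surface_genes_b": self.surface_genes_b,
        }
        return json.dumps(rec, sort_keys=True, default=float)


def _gene_names(prefix: str, n: int, mito_prefix: str, n_mito: int) -> list[str]:
    names = [f"{prefix}{i:05d}" for i in range(n - n_mito)]
    names += [f"{mito_prefix}{i + 1:02d}" for i in range(n_mito)]
    return names


def generate_truth(config: SyntheticConfig, seed: int) -> SyntheticTruth:
    """Draw the latent truth: cells, gene programs, homology and marker sets.

    Deterministic for a fixed ``(config, seed)``. Raises ``ConfigError`` (via
    ``config.validate()``) if the requested marker counts exceed the gene
    budget.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n_states = len(STATES)

    # ---- cells ------------------------------------------------------------
    # latent time is drawn from state-centered mixtures with a thin uniform
    # bridge: differentiating epithelia accumulate cells in metastable
    # states, with comparatively few cells in transit between them
    t_mixture = {
        BRANCH_SECRETORY: [(0.12, 0.06, 0.32), (0.62, 0.18, 0.48)],
        BRANCH_CILIOGENIC: [(0.12, 0.06, 0.30), (0.45, 0.08, 0.27),
                            (0.80, 0.10, 0.25)],
    }

    def _sample_t(branch_vec: np.ndarray) -> np.ndarray:
        t = rng.random(len(branch_vec))  # bridge component
        for br, comps in t_mixture.items():
            m = branch_vec == br
            u = rng.random(int(m.sum()))
            draws = np.full(int(m.sum()), -1.0)
            lo = 0.0
            for center, width, weight in comps:
                sel = (u >= lo) & (u < lo + weight)
                draws[sel] = rng.normal(center, width, int(sel.sum()))
                lo += weight
            keep = draws >= 0
            tm = t[m]
            tm[keep] = np.clip(draws[keep], 0.0, 1.0)
            t[m] = tm
        return t

    cells = {}
    for species in ("a", "b"):
        n = config.n_cells
        branch = np.where(rng.random(n) < 0.5, BRANCH_SECRETORY,
                          BRANCH_CILIOGENIC)
        t = _sample_t(branch)
        lq = rng.random(n) < config.low_quality_fraction
        state = np.array([state_from_latent(b, tt)
                          for b, tt in zip(branch, t)], dtype=object)
        state[lq] = LOW_QUALITY
        region = rng.choice(["distal", "medial", "proximal"], size=n)
        cells[species] = pd.DataFrame({
            "cell_id": [f"{species.upper()}_{i:05d}" for i in range(n)],
            "state": state, "branch": branch, "t": t,
            "low_quality": lq, "region": region,
        })

    # ---- gene layout -------------------------------------------------------
    names = {
        "a": _gene_names("gA", config.n_genes_a, "mt-sim", config.n_mito),
        "b": _gene_names("gB", config.n_genes_b, "MT-SIM", config.n_mito),
    }
    n_cons = config.n_conserved_per_state
    n_ident = config.n_identity_per_state
    n_spec = config.n_specific_per_state

    roles = {sp_: np.array(["baseline"] * len(names[sp_]), dtype=object)
             for sp_ in ("a", "b")}
    state_of = {sp_: np.array([""] * len(names[sp_]), dtype=object)
                for sp_ in ("a", "b")}
    programs: dict[str, dict[int, list]] = {"a": {}, "b": {}}

    def _add(species: str, idx: int, branch, kind, params, amp, role, st=""):
        programs[species].setdefault(idx, []).append((branch, kind, params, amp))
        roles[species][idx] = role
        if st:
            state_of[species][idx] = st

    pos = 0
    # conserved markers: shared program parameters on ortholog indices
    for si, st in enumerate(STATES):
        br, kind, params = STATE_PROGRAM[st]
        for j in range(n_cons):
            amp = config.marker_amplitude * rng.uniform(0.8, 1.25)
            for sp_ in ("a", "b"):
                _add(sp_, pos, br, kind, params, amp, "conserved_marker", st)
            pos += 1
    # identity modules: weaker, still shared
    for si, st in enumerate(STATES):
        br, kind, params = STATE_PROGRAM[st]
        for j in range(n_ident):
            amp = config.identity_amplitude * rng.uniform(0.8, 1.25)
            for sp_ in ("a", "b"):
                _add(sp_, pos, br, kind, params, amp, "identity", st)
            pos += 1
    # trunk gradient genes: shared monotone decay from the progenitor pool;
    # midpoints concentrate early so the shared manifold resolves latent
    # time inside the progenitor window
    for m in np.linspace(0.02, 0.70, config.n_trunk_gradient):
        amp = config.gradient_amplitude * rng.uniform(0.8, 1.25)
        for sp_ in ("a", "b"):
            _add(sp_, pos, None, "fall", (float(m), 0.12), amp, "gradient_trunk")
        pos += 1
    # branch gradient genes: monotone rise along each branch, activating
    # after the branch point so the bipotent progenitor pool stays mixed
    for br in (BRANCH_SECRETORY, BRANCH_CILIOGENIC):
        for m in np.linspace(0.35, 0.95, config.n_branch_gradient):
            amp = config.gradient_amplitude * rng.uniform(0.8, 1.25)
            for sp_ in ("a", "b"):
                _add(sp_, pos, br, "rise", (float(m), 0.10), amp,
                     f"gradient_{br}")
            pos += 1
    # program handoff on the ciliogenic branch: the early gene switches on
    # at the branch point and decays as the late gene rises (a branch-
    # restricted program must not be active in the bipotent progenitor pool,
    # which carries no branch information yet)
    handoff_idx = (pos, pos + 1)
    for sp_ in ("a", "b"):
        _add(sp_, pos, BRANCH_CILIOGENIC, "bump", (0.26, 0.04, 0.68, 0.07),
             config.handoff_amplitude, "handoff_early")
        _add(sp_, pos + 1, BRANCH_CILIOGENIC, "rise", (0.68, 0.07),
             config.handoff_amplitude, "handoff_late")
    pos += 2
    # divergent orthologs: independent random programs per species
    n_divergent = int(round(config.divergent_fraction * config.n_orthologs))
    divergent_idx = list(range(pos, pos + n_divergent))
    for idx in divergent_idx:
        for sp_ in ("a", "b"):
            kind = str(rng.choice(["rise", "fall"]))
            m = float(rng.uniform(0.1, 0.9))
            s = float(rng.uniform(0.08, 0.2))
            br = rng.choice([None, BRANCH_SECRETORY, BRANCH_CILIOGENIC])
            amp = config.identity_amplitude * rng.uniform(0.8, 1.25)
            if br is not None and kind == "fall":
                # decaying branch-restricted programs switch on at the
                # branch point; progenitors carry no branch information
                _add(sp_, idx, br, "bump", (0.26, 0.04, max(m, 0.35), s),
                     amp, "divergent_ortholog")
            else:
                _add(sp_, idx, br, kind, (m, s), amp, "divergent_ortholog")
    pos += n_divergent

    # species-specific regions start right after the ortholog block
    spec_markers = {"a": {}, "b": {}}
    for sp_ in ("a", "b"):
        p = config.n_orthologs
        for st in STATES:
            br, kind, params = STATE_PROGRAM[st]
            spec_markers[sp_][st] = []
            for j in range(n_spec):
                amp = config.marker_amplitude * rng.uniform(0.8, 1.25)
                _add(sp_, p, br, kind, params, amp, "specific_marker", st)
                spec_markers[sp_][st].append(names[sp_][p])
                p += 1
        if sp_ == "a":
            analog_start_a = p
        else:
            analog_start_b = p

    # analogous pairs: progenitor-restricted programs, one distinct curve per
    # pair, shared across species, never entered into the homology table
    # Each analog pair is progenitor-dominant (a bump inside the progenitor
    # window) plus a weaker pair-specific secondary feature elsewhere on the
    # trajectory. Real analogous markers are not pure state indicators; the
    # secondary feature makes each pair's profile individually recognizable
    # so the true partner is the best-correlated one.
    analog_primary = [(0.02, 0.02, 0.14, 0.03), (0.06, 0.03, 0.20, 0.04),
                      (0.10, 0.03, 0.24, 0.04), (0.04, 0.02, 0.28, 0.05),
                      (0.08, 0.05, 0.18, 0.03)]
    analog_secondary = [
        (BRANCH_SECRETORY, "rise", (0.75, 0.06)),
        (BRANCH_CILIOGENIC, "rise", (0.75, 0.06)),
        (BRANCH_SECRETORY, "bump", (0.35, 0.05, 0.55, 0.05)),
        (BRANCH_CILIOGENIC, "bump", (0.30, 0.05, 0.50, 0.05)),
        (BRANCH_SECRETORY, "rise", (0.45, 0.06)),
    ]
    analog_pairs = []
    for j in range(config.n_analogs):
        m1, s1, m2, s2 = analog_primary[j % len(analog_primary)]
        m2 += 0.002 * (j // len(analog_primary))
        sec_br, sec_kind, sec_params = analog_secondary[j % len(analog_secondary)]
        amp = config.marker_amplitude * rng.uniform(0.9, 1.2)
        ia, ib = analog_start_a + j, analog_start_b + j
        for sp_, idx in (("a", ia), ("b", ib)):
            _add(sp_, idx, None, "bump", (m1, s1, m2, s2), amp, "analog",
                 "progenitor")
            _add(sp_, idx, sec_br, sec_kind, sec_params, 0.4 * amp, "analog",
                 "progenitor")
        analog_pairs.append((names["a"][ia], names["b"][ib]))

    # mitochondrial genes are the trailing names; baseline-only
    for sp_, n_genes in (("a", config.n_genes_a), ("b", config.n_genes_b)):
        roles[sp_][n_genes - config.n_mito:] = "mito"

    # ---- baselines ---------------------------------------------------------
    baselines = {}
    for sp_, n_genes in (("a", config.n_genes_a), ("b", config.n_genes_b)):
        base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
        # planted markers are near-silent outside their program (that is what
        # makes them canonical markers), so their off-state baseline is low
        marker_like = np.isin(roles[sp_], ["conserved_marker",
                                           "specific_marker", "analog"])
        base[marker_like] *= 0.1
        mito = slice(n_genes - config.n_mito, n_genes)
        non_mito_sum = base[:n_genes - config.n_mito].sum()
        target = config.mito_share / (1 - config.mito_share) * non_mito_sum
        base[mito] *= target / base[mito].sum()
        baselines[sp_] = base

    # ---- homology table ----------------------------------------------------
    n_orth = config.n_orthologs
    bitscores = np.clip(
        rng.lognormal(np.log(config.bitscore_median), config.bitscore_sigma,
                      n_orth),
        config.bitscore_floor, None)
    orthologs = pd.DataFrame({
        "gene_a": [names["a"][i] for i in range(n_orth)],
        "gene_b": [names["b"][i] for i in range(n_orth)],
        "pident": rng.uniform(60, 95, n_orth),
        "evalue": 10.0 ** (-rng.uniform(20, 80, n_orth)),
        "bitscore": bitscores,
        "divergent": [i in set(divergent_idx) for i in range(n_orth)],
    })

    conserved_markers = {
        st: [(names["a"][si * n_cons + j], names["b"][si * n_cons + j])
             for j in range(n_cons)]
        for si, st in enumerate(STATES)
    }

    # ---- surface flags (species B = human-like) ----------------------------
    surface = [p[1] for p in analog_pairs]
    surface += [gb for st in ("secretory", "ciliated")
                for _, gb in conserved_markers[st]]
    baseline_b = [names["b"][i] for i in range(len(names["b"]))
                  if roles["b"][i] == "baseline"]
    surface += list(rng.choice(baseline_b,
                               size=min(config.n_surface_decoys,
                                        len(baseline_b)),
                               replace=False))
    surface = sorted(set(surface))

    genes = {}
    for sp_ in ("a", "b"):
        n_genes = len(names[sp_])
        genes[sp_] = pd.DataFrame({
            "gene_id": names[sp_],
            "role": roles[sp_],
            "state": state_of[sp_],
            "is_mito": [r == "mito" for r in roles[sp_]],
            "is_surface": [g in set(surface) if sp_ == "b" else False
                           for g in names[sp_]],
        })

    return SyntheticTruth(
        config=config, cells=cells, genes=genes, programs=programs,
        baselines=baselines, orthologs=orthologs,
        conserved_markers=conserved_markers,
        a_specific_markers=spec_markers["a"],
        b_specific_markers=spec_markers["b"],
        analog_pairs=analog_pairs,
        handoff_pair={sp_: (names[sp_][handoff_idx[0]],
                            names[sp_][handoff_idx[1]])
                      for sp_ in ("a", "b")},
        surface_genes_b=surface,
    )


def program_intensity(truth: SyntheticTruth, species: str, gene: str,
                      t: np.ndarray, branch: str) -> np.ndarray:
    """Noise-free program intensity of one gene along a latent-time grid."""
    names = truth.genes[species]["gene_id"].tolist()
    idx = names.index(gene)
    t = np.asarray(t, dtype=float)
    lam = np.full(t.shape, truth.baselines[species][idx])
    for br, kind, params, amp in truth.programs[species].get(idx, []):
        if br is None or br == branch:
            lam = lam + amp * _activation(kind, params, t)
    return lam


def _intensity_matrix(truth: SyntheticTruth, species: str,
                      rng: np.random.Generator) -> np.ndarray:
    cells = truth.cells[species]
    t = cells["t"].to_numpy()
    branch = cells["branch"].to_numpy()
    n_cells, n_genes = len(cells), len(truth.baselines[species])
    lam = np.tile(truth.baselines[species], (n_cells, 1))
    for gi, modules in truth.programs[species].items():
        for br, kind, params, amp in modules:
            mask = np.ones(n_cells, bool) if br is None else branch == br
            lam[mask, gi] += amp * _activation(kind, params, t[mask])
    # planted low-quality cells: reallocate intensity mass to mitochondrial
    # genes so the realized fraction clears every preset cap
    lq = cells["low_quality"].to_numpy()
    if lq.any():
        mito = truth.genes[species]["is_mito"].to_numpy()
        u = rng.uniform(0.40, 0.60, size=int(lq.sum()))
        lam_lq = lam[lq]
        non_mito = lam_lq[:, ~mito].sum(axis=1)
        mito_sum = lam_lq[:, mito].sum(axis=1)
        factor = (u / (1 - u)) * non_mito / mito_sum
        lam_lq[:, mito] *= factor[:, None]
        lam[lq] = lam_lq
    return lam


def simulate_counts(truth: SyntheticTruth, config: SyntheticConfig,
                    seed: int) -> tuple[ad.AnnData, ad.AnnData]:
    """Sample negative-binomial counts for both species.

    Per gene and cell the mean is ``library_size x relative program
    intensity``; counts are Gamma–Poisson with dispersion ``config.dispersion``
    (variance ``mu + dispersion * mu^2``). Planted low-quality cells receive
    library sizes below the count floor. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    out = []
    for species in ("a", "b"):
        cells = truth.cells[species]
        lam = _intensity_matrix(truth, species, rng)
        p = lam / lam.sum(axis=1, keepdims=True)

        n = len(cells)
        lib = rng.lognormal(np.log(config.library_median),
                            config.library_sigma, n)
        lq = cells["low_quality"].to_numpy()
        lib_lq = np.minimum(
            rng.lognormal(np.log(config.low_quality_library), 0.3, n),
            1.5 * config.low_quality_library)
        lib = np.where(lq, lib_lq, lib)

        mu = lib[:, None] * p
        r = 1.0 / config.dispersion
        counts = rng.poisson(rng.gamma(r, mu / r))

        obs = pd.DataFrame({
            "species": species,
            "true_state": cells["state"].to_numpy(),
            "true_branch": cells["branch"].to_numpy(),
            "true_time": cells["t"].to_numpy(),
            "low_quality": cells["low_quality"].to_numpy(),
            "region": cells["region"].to_numpy(),
        }, index=pd.Index(cells["cell_id"], name="cell_id"))
        var = truth.genes[species].set_index("gene_id")
        var.index.name = "gene_id"
        adata = ad.AnnData(X=sp.csr_matrix(counts.astype(np.int64)),
                           obs=obs, var=var.copy())
        out.append(adata)
    return out[0], out[1]


def write_dataset(matrices: tuple[ad.AnnData, ad.AnnData],
                  truth: SyntheticTruth, out_dir: str | Path) -> dict:
    """Emit the dataset in its on-disk interchange formats.

    MTX triplets per species, homology as BLAST outfmt-6, the surface-marker
    list, per-state marker signatures, a gene -> functional-category map, and
    ``truth.json``. Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    adata_a, adata_b = matrices
    paths = {
        "species_a": tio.write_counts_mtx(adata_a, out_dir / "species_a"),
        "species_b": tio.write_counts_mtx(adata_b, out_dir / "species_b"),
        "homology": tio.write_blast6(truth.orthologs, out_dir / "homology.tsv"),
    }

    surface_path = out_dir / "surface_markers.txt"
    surface_path.write_text("\n".join(truth.surface_genes_b) + "\n")
    paths["surface"] = surface_path

    sig_rows = []
    for st, pairs in truth.conserved_markers.items():
        for ga, gb in pairs:
            sig_rows.append((f"{st}_a", ga))
            sig_rows.append((f"{st}_b", gb))
    paths["signatures"] = tio.write_tsv(
        pd.DataFrame(sig_rows, columns=["signature", "gene"]),
        out_dir / "signatures.tsv")

    cat_rows = []
    for st, pairs in truth.conserved_markers.items():
        for ga, gb in pairs:
            cat_rows.append((ga, STATE_CATEGORY[st]))
            cat_rows.append((gb, STATE_CATEGORY[st]))
    for sp_, markers in (("a", truth.a_specific_markers),
                         ("b", truth.b_specific_markers)):
        for st, gs in markers.items():
            cat_rows.extend((g, STATE_CATEGORY[st]) for g in gs)
    paths["categories"] = tio.write_tsv(
        pd.DataFrame(cat_rows, columns=["gene", "category"]),
        out_dir / "gene_categories.tsv")

    truth_path = out_dir / "truth.json"
    truth_path.write_text(truth.to_json())
    paths["truth"] = truth_path
    return paths
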