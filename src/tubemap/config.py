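"""Pipeline and simulation configuration.

Every numeric threshold used anywhere in the pipeline lives here, with the
defaults matching the study design the package implements: mitochondrial
fraction caps of 30% (mouse-like species A) and 20% (human-like species B),
library-size and feature floors of 750 / 200, a kNN parameter of 70,
community-detection resolution 0.7, a PCA variance target of 95%, 40
pseudotime bins, a 0.2 correlation floor for homologous pair alignment, and
the analog filters (correlation > 0.4, inverse BLAST score > 0.010, top 10).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised when a configuration value is missing, unknown or out of range."""


# QC presets: the mouse-like species keeps the 30% mitochondrial cap; for the
# human-like species only the mitochondrial cap tightens to 20%, the count and
# feature floors are shared.
QC_PRESETS = {
    "mouse": {"mito_max": 0.30, "min_counts": 750, "min_features": 200},
    "human": {"mito_max": 0.20, "min_counts": 750, "min_features": 200},
}


@dataclass
class SyntheticConfig:
    """Study conditions for the two-species synthetic generator.

    Cell numbers, gene-space sizes, ortholog count, planted marker counts and
    the analog-pair count are the default benchmark conditions; noise
    parameters (negative-binomial dispersion 0.3, log-normal library sizes
    with median 5000) emulate a typical droplet-based experiment.
    """

    n_cells: int = 3000              # cells per species
    n_genes_a: int = 1500
    n_genes_b: int = 1800
    n_orthologs: int = 1000          # one-to-one ortholog pairs
    n_conserved_per_state: int = 10  # planted conserved markers per state
    n_specific_per_state: int = 10   # planted species-specific markers per state
    n_analogs: int = 5               # planted analogous (non-homologous) pairs
    low_quality_fraction: float = 0.05
    dispersion: float = 0.3          # NB dispersion (var = mu + dispersion*mu^2)
    divergent_fraction: float = 0.1  # orthologs with independent programs
    library_median: float = 5000.0
    library_sigma: float = 0.3
    low_quality_library: float = 350.0
    n_mito: int = 10                 # mitochondrial genes per species
    mito_share: float = 0.03         # baseline mitochondrial mass fraction
    bitscore_median: float = 200.0
    bitscore_sigma: float = 0.25
    bitscore_floor: float = 120.0    # keeps every ortholog inverse score < 0.010
    n_identity_per_state: int = 30   # weaker per-state identity-module genes
    n_trunk_gradient: int = 40       # shared monotone trunk genes
    n_branch_gradient: int = 40      # per-branch monotone genes
    n_surface_decoys: int = 25       # surface-flagged genes without progenitor programs
    marker_amplitude: float = 40.0
    identity_amplitude: float = 25.0
    gradient_amplitude: float = 15.0
    handoff_amplitude: float = 30.0

    def validate(self) -> "SyntheticConfig":
        n_states = 4
        if self.n_cells < 100:
            raise ConfigError("synthetic.n_cells must be >= 100")
        for key in ("n_genes_a", "n_genes_b", "n_orthologs", "n_analogs",
                    "n_conserved_per_state", "n_specific_per_state", "n_mito"):
            if getattr(self, key) < 0:
                raise ConfigError(f"synthetic.{key} must be >= 0")
        if not 0.0 <= self.low_quality_fraction <= 0.5:
            raise ConfigError("synthetic.low_quality_fraction must be in [0, 0.5]")
        if not 0.0 <= self.divergent_fraction <= 1.0:
            raise ConfigError("synthetic.divergent_fraction must be in [0, 1]")
        if self.dispersion <= 0:
            raise ConfigError("synthetic.dispersion must be > 0")
        programmed = (n_states * (self.n_conserved_per_state + self.n_identity_per_state)
                      + self.n_trunk_gradient + 2 * self.n_branch_gradient + 2)
        n_divergent = int(round(self.divergent_fraction * self.n_orthologs))
        if programmed + n_divergent > self.n_orthologs:
            raise ConfigError(
                f"ortholog block too small: {programmed} programmed + "
                f"{n_divergent} divergent > n_orthologs={self.n_orthologs}")
        specific = n_states * self.n_specific_per_state + self.n_analogs + self.n_mito
        if specific > self.n_genes_a - self.n_orthologs:
            raise ConfigError("species-A-specific gene region too small for "
                              "requested markers/analogs/mito genes")
        if specific > self.n_genes_b - self.n_orthologs:
            raise ConfigError("species-B-specific gene region too small for "
                              "requested markers/analogs/mito genes")
        return self


@dataclass
class PipelineConfig:
    """All tunable thresholds of the analysis pipeline (validated)."""

    # QC (species-A defaults; species B uses the "human" preset's mito cap)
    mito_max: float = 0.30
    min_counts: int = 750
    min_features: int = 200
    # normalization / feature selection / embedding
    scale: float = 1e4
    n_hvg: int = 2000
    variance_target: float = 0.95
    max_components: int = 100
    # graph / clustering
    knn_k: int = 70
    cluster_resolution: float = 0.7
    # trajectory
    n_bins: int = 40
    r_max: int = 1500
    # cross-species mapping
    k_cross: int = 20
    conservation_corr_min: float = 0.2
    n_candidate_genes: int = 500
    # analog discovery
    analog_corr_min: float = 0.4
    inv_bitscore_min: float = 0.010
    top_k: int = 10
    # conservation reference
    n_top_markers: int = 25
    # misc
    mito_prefixes: tuple[str, ...] = ("mt-", "MT-")
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def validate(self) -> "PipelineConfig":
        def _in_unit(key: str) -> None:
            v = getattr(self, key)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{key}={v!r} out of range [0, 1]")

        _in_unit("mito_max")
        _in_unit("variance_target")
        if self.variance_target == 0:
            raise ConfigError("variance_target must be > 0")
        for key in ("min_counts", "min_features"):
            if getattr(self, key) < 0:
                raise ConfigError(f"{key} must be >= 0")
        if self.scale <= 0:
            raise ConfigError("scale must be > 0")
        for key in ("n_hvg", "knn_k", "k_cross", "top_k", "n_top_markers",
                    "n_candidate_genes", "max_components"):
            if getattr(self, key) < 1:
                raise ConfigError(f"{key} must be >= 1")
        if self.n_bins < 2:
            raise ConfigError("n_bins must be >= 2")
        if self.r_max < 2:
            raise ConfigError("r_max must be >= 2")
        for key in ("conservation_corr_min", "analog_corr_min"):
            v = getattr(self, key)
            if not -1.0 <= v <= 1.0:
                raise ConfigError(f"{key}={v!r} out of range [-1, 1]")
        if self.inv_bitscore_min < 0:
            raise ConfigError("inv_bitscore_min must be >= 0")
        if self.cluster_resolution <= 0:
            raise ConfigError("cluster_resolution must be > 0")
        if self.seed < 0:
            raise ConfigError("seed must be >= 0")
        self.synthetic.validate()
        return self

    def qc_thresholds(self, preset: str | None = None) -> dict:
        """QC thresholds, optionally overridden by a named species preset."""
        if preset is None:
            return {"mito_max": self.mito_max, "min_counts": self.min_counts,
                    "min_features": self.min_features}
        if preset not in QC_PRESETS:
            raise ConfigError(f"unknown QC preset {preset!r}; "
                              f"choose from {sorted(QC_PRESETS)}")
        return dict(QC_PRESETS[preset])


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config file; missing keys fall back to documented defaults.

    Unknown keys and out-of-range values raise :class:`ConfigError` naming the
    offending key. ``path=None`` or an empty file yields the full default
    configuration. The effective configuration is echoed to the log.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        raw = loaded

    syn_raw = raw.pop("synthetic", {}) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)} - {"synthetic"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    syn_known = {f.name for f in dataclasses.fields(SyntheticConfig)}
    syn_unknown = set(syn_raw) - syn_known
    if syn_unknown:
        raise ConfigError(f"unknown synthetic config keys: {sorted(syn_unknown)}")

    if "mito_prefixes" in raw:
        raw["mito_prefixes"] = tuple(raw["mito_prefixes"])
    cfg = PipelineConfig(synthetic=SyntheticConfig(**syn_raw), **raw)
    cfg.validate()
    logger.info("effective config: %s", dataclasses.asdict(cfg))
    return cfg
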