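"""Shared fixtures: a desk-scale synthetic dataset and processed pipeline run."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from tubemap.config import PipelineConfig, SyntheticConfig
from tubemap import pipeline


def toy_synthetic_config(**overrides) -> SyntheticConfig:
    """A small but structurally complete two-species dataset."""
    defaults = dict(
        n_cells=400, n_genes_a=300, n_genes_b=340, n_orthologs=250,
        n_conserved_per_state=5, n_specific_per_state=5, n_analogs=3,
        n_identity_per_state=8, n_trunk_gradient=12, n_branch_gradient=10,
        n_surface_decoys=10,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


def toy_pipeline_config(**overrides) -> PipelineConfig:
    defaults = dict(
        synthetic=toy_synthetic_config(), knn_k=25, n_hvg=250,
        n_candidate_genes=120, n_bins=20,
    )
    defaults.update(overrides)
    return PipelineConfig(**defaults)


@pytest.fixture(scope="session")
def toy_run():
    """One full pipeline run on the toy dataset, shared across tests."""
    return pipeline.run_pipeline(toy_pipeline_config(), seed=0)


def make_counts_adata(counts: np.ndarray, mito_mask=None,
                      cell_prefix: str = "c", gene_prefix: str = "g"
                      ) -> ad.AnnData:
    """Build a minimal counts AnnData from a dense integer array."""
    counts = np.asarray(counts, dtype=np.int64)
    n, g = counts.shape
    obs = pd.DataFrame(index=pd.Index([f"{cell_prefix}{i:03d}"
                                       for i in range(n)], name="cell_id"))
    var = pd.DataFrame(index=pd.Index([f"{gene_prefix}{j:03d}"
                                       for j in range(g)], name="gene_id"))
    var["is_mito"] = (np.zeros(g, bool) if mito_mask is None
                      else np.asarray(mito_mask, bool))
    return ad.AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)
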