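"""Readers and writers for the external formats the pipeline consumes.

Count matrices travel as 10x-style Matrix Market triplets (``matrix.mtx`` in
genes x cells orientation plus ``barcodes.tsv`` and ``features.tsv``) and are
held in memory as :class:`anndata.AnnData` in cells x genes orientation with
integer sparse counts. Homology comes in as BLAST tabular output (outfmt 6)
reduced to best hits. Gene annotations are plain one-gene-per-line lists or
two-column TSVs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: column names of BLAST tabular output (-outfmt 6)
BLAST6_COLUMNS = ("qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                  "qstart", "qend", "sstart", "send", "evalue", "bitscore")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def _check_unique(ids: pd.Index, what: str, where: str) -> None:
    if ids.has_duplicates:
        dupes = ids[ids.duplicated()].unique()[:5].tolist()
        raise FormatError(f"duplicate {what} in {where}: {dupes}")


def flag_mito(gene_ids, prefixes: tuple[str, ...] = ("mt-", "MT-")) -> np.ndarray:
    """Boolean mask of mitochondrial genes by name-prefix rule."""
    gene_ids = np.asarray(gene_ids, dtype=object)
    mask = np.zeros(len(gene_ids), dtype=bool)
    for p in prefixes:
        mask |= np.char.startswith(gene_ids.astype(str), p)
    return mask


def read_counts_mtx(directory: str | Path,
                    mito_prefixes: tuple[str, ...] = ("mt-", "MT-")) -> ad.AnnData:
    """Read a 10x-style MTX triplet into an AnnData of cells x genes counts.

    The matrix file is genes x cells (10x convention) and is transposed on
    read. ``var["is_mito"]`` is set by the configurable gene-name prefix rule.

    Raises
    ------
    FormatError
        On dimension mismatch between the matrix header and the id files, on
        non-integer or negative entries, or on duplicate ids.
    """
    directory = Path(directory)
    barcodes = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)
    features = pd.read_csv(directory / "features.tsv", sep="\t", header=None)
    mat = scipy.io.mmread(directory / "matrix.mtx")

    n_genes, n_cells = mat.shape
    if n_genes != len(features) or n_cells != len(barcodes):
        raise FormatError(
            f"{directory}: matrix is {n_genes} genes x {n_cells} cells but "
            f"features.tsv has {len(features)} lines and barcodes.tsv "
            f"{len(barcodes)} lines")

    data = np.asarray(mat.data)
    if data.size and (np.any(data < 0) or not np.allclose(data, np.round(data))):
        raise FormatError(f"{directory}: counts must be non-negative integers")
    counts = sp.csr_matrix(mat.T.astype(np.int64))

    cell_ids = pd.Index(barcodes[0].astype(str), name="cell_id")
    gene_ids = pd.Index(features[0].astype(str), name="gene_id")
    _check_unique(cell_ids, "cell ids", str(directory / "barcodes.tsv"))
    _check_unique(gene_ids, "gene ids", str(directory / "features.tsv"))

    obs = pd.DataFrame(index=cell_ids)
    var = pd.DataFrame(index=gene_ids)
    var["is_mito"] = flag_mito(gene_ids.to_numpy(), mito_prefixes)
    adata = ad.AnnData(X=counts, obs=obs, var=var)

    # optional metadata sidecars written by write_counts_mtx
    for name, df in (("cell_meta.tsv", "obs"), ("gene_meta.tsv", "var")):
        p = directory / name
        if p.exists():
            meta = pd.read_csv(p, sep="\t", index_col=0)
            meta.index = meta.index.astype(str)
            target = getattr(adata, df)
            for col in meta.columns:
                target[col] = meta.loc[target.index, col].to_numpy()
    for col in ("is_mito", "is_surface"):
        if col in adata.var.columns:
            adata.var[col] = adata.var[col].astype(bool)
    return adata


def write_counts_mtx(adata: ad.AnnData, directory: str | Path) -> Path:
    """Write an AnnData of integer counts as a 10x-style MTX triplet.

    Cell and gene metadata frames are written alongside as ``cell_meta.tsv``
    / ``gene_meta.tsv`` so a read round-trip is lossless.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(X)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), X.T.tocoo(), field="integer")
    pd.Series(adata.obs_names).to_csv(directory / "barcodes.tsv",
                                      sep="\t", header=False, index=False)
    feat = pd.DataFrame({"gene_id": adata.var_names, "name": adata.var_names,
                         "type": "Gene Expression"})
    feat.to_csv(directory / "features.tsv", sep="\t", header=False, index=False)
    if len(adata.obs.columns):
        adata.obs.to_csv(directory / "cell_meta.tsv", sep="\t")
    if len(adata.var.columns):
        adata.var.to_csv(directory / "gene_meta.tsv", sep="\t")
    return directory


def read_blast6(path: str | Path) -> pd.DataFrame:
    """Parse BLAST tabular output into a best-hit-reduced homology table.

    Returns a DataFrame with columns ``gene_a`` (query), ``gene_b``
    (subject), ``pident``, ``evalue`` and ``bitscore``. When a (gene_a,
    gene_b) pair occurs more than once, only the record with the maximal
    bitscore is retained, so the reduction is idempotent. Lines starting with
    ``#`` are ignored. An empty file yields an empty table.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(BLAST6_COLUMNS):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(BLAST6_COLUMNS)} "
                    f"tab-separated columns, got {len(parts)}")
            try:
                pident = float(parts[2])
                evalue = float(parts[10])
                bitscore = float(parts[11])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field "
                                  f"({exc})") from None
            if bitscore <= 0:
                raise FormatError(f"{path}:{lineno}: bitscore must be > 0, "
                                  f"got {bitscore}")
            rows.append((parts[0], parts[1], pident, evalue, bitscore))

    hom = pd.DataFrame(rows, columns=["gene_a", "gene_b", "pident",
                                      "evalue", "bitscore"])
    if len(hom):
        hom = (hom.sort_values(["gene_a", "gene_b", "bitscore"])
                  .groupby(["gene_a", "gene_b"], as_index=False, sort=True)
                  .last())
    return hom.reset_index(drop=True)


def write_blast6(hom: pd.DataFrame, path: str | Path) -> Path:
    """Serialize a homology table as 12-column BLAST outfmt-6 lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for row in hom.itertuples(index=False):
            length = 500
            mismatch = int(round(length * (1 - row.pident / 100.0)))
            fh.write("\t".join(map(str, (
                row.gene_a, row.gene_b, f"{row.pident:.2f}", length, mismatch,
                0, 1, length, 1, length, f"{row.evalue:.2e}",
                f"{row.bitscore:.1f}"))) + "\n")
    return path


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain one-gene-per-line list (blank lines ignored)."""
    genes = [ln.strip() for ln in Path(path).read_text().splitlines()]
    return [g for g in genes if g]


def read_gene_categories(path: str | Path) -> pd.DataFrame:
    """Read a two-column gene -> functional-category TSV (with header)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (gene, category)")
    df = df.iloc[:, :2]
    df.columns = ["gene", "category"]
    return df


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    """Write a TSV with header, UTF-8, floats at 6 significant digits."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.6g",
              encoding="utf-8")
    return path


def write_manifest(out_dir: str | Path, config, seed: int,
                   command: str) -> Path:
    """Record the effective config, seed and package versions for a run."""
    import dataclasses
    from importlib.metadata import version

    from . import __version__

    manifest = {
        "command": command,
        "seed": seed,
        "config": dataclasses.asdict(config),
        "versions": {
            "tubemap": __version__,
            "numpy": version("numpy"),
            "scipy": version("scipy"),
            "pandas": version("pandas"),
            "anndata": version("anndata"),
        },
    }
    out = Path(out_dir) / "manifest.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return out
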