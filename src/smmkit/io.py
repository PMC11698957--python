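"""Reading and writing the package's on-disk formats.

Count matrices travel as genes x cells MatrixMarket (``matrix.mtx``) with
``genes.tsv`` / ``barcodes.tsv`` sidecars; receptor contigs as CSV in a
cell-ranger-style filtered-contig schema subset; clinical tables as plain
CSV. In memory, counts are cells x genes :class:`anndata.AnnData`.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

CONTIG_COLUMNS = ["barcode", "chain", "cdr3", "umis", "reads", "raw_clonotype_id", "c_gene"]

__all__ = ["CONTIG_COLUMNS", "write_count_matrix", "read_count_matrix",
           "write_contigs", "read_contigs"]


def write_count_matrix(adata: ad.AnnData, outdir: str | Path) -> None:
    """Write an AnnData as genes x cells MTX + genes.tsv + barcodes.tsv.

    Cell metadata (``adata.obs``) goes to ``cell_metadata.csv`` alongside.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(np.asarray(X))
    spio.mmwrite(outdir / "matrix.mtx", X.T.astype(np.int64))
    pd.Series(adata.var_names).to_csv(outdir / "genes.tsv", sep="\t",
                                      index=False, header=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t",
                                      index=False, header=False)
    if adata.obs.shape[1]:
        adata.obs.to_csv(outdir / "cell_metadata.csv")


def read_count_matrix(indir: str | Path) -> ad.AnnData:
    """Read a genes x cells MTX directory back into a cells x genes AnnData."""
    indir = Path(indir)
    X = spio.mmread(indir / "matrix.mtx").T.tocsr()
    genes = pd.read_csv(indir / "genes.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    adata = ad.AnnData(X=X)
    adata.var_names = genes
    adata.obs_names = barcodes
    meta_path = indir / "cell_metadata.csv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, index_col=0)
        adata.obs = meta.loc[adata.obs_names]
    return adata


def write_contigs(contigs: pd.DataFrame, path: str | Path) -> None:
    missing = set(CONTIG_COLUMNS) - set(contigs.columns)
    if missing:
        raise ValueError(f"contig table missing columns: {sorted(missing)}")
    contigs[CONTIG_COLUMNS].to_csv(path, index=False)


def read_contigs(path: str | Path) -> pd.DataFrame:
    contigs = pd.read_csv(path)
    missing = set(CONTIG_COLUMNS) - set(contigs.columns)
    if missing:
        raise ValueError(f"contig table missing columns: {sorted(missing)}")
    return contigs
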