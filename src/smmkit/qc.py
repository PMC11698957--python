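"""Cell-level quality filtering and fixed-depth read downsampling.

QC removes droplets with >15% mitochondrial content, <200 or >5000
detected genes, or <400 or >50,000 total counts (strict inequalities:
boundary cells are kept). Depth normalization drops cells below a fixed
read target and subsamples the rest without replacement (multivariate
hypergeometric) to exactly that target, so every retained cell has an
identical total.

"Reads per cell" is operationalized as the total counts per cell present
in the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "QCThresholds",
    "compute_qc_metrics",
    "filter_cells_qc",
    "downsample_reads_per_cell",
]


@dataclass(frozen=True)
class QCThresholds:
    """Removal cutoffs; cells strictly beyond any cutoff are dropped."""

    max_mito: float = 0.15
    min_genes: int = 200
    max_genes: int = 5000
    min_umis: int = 400
    max_umis: int = 50_000


def _dense_counts(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    if sparse.issparse(X):
        X = X.toarray()
    return np.asarray(X)


def compute_qc_metrics(adata: ad.AnnData, mito_prefix: str = "MT-") -> pd.DataFrame:
    """Per-cell QC metrics from the count matrix itself.

    Returns a frame indexed like ``adata.obs`` with ``mito_fraction``,
    ``n_genes`` (detected genes) and ``n_umis`` (total counts).
    Mitochondrial genes are identified by name prefix (default ``MT-``).
    """
    X = _dense_counts(adata)
    total = X.sum(axis=1)
    mito_mask = adata.var_names.str.startswith(mito_prefix)
    mito = X[:, mito_mask].sum(axis=1) if mito_mask.any() else np.zeros(len(total))
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {
            "mito_fraction": mito_frac,
            "n_genes": (X > 0).sum(axis=1).astype(int),
            "n_umis": total.astype(int),
        },
        index=adata.obs_names,
    )


def filter_cells_qc(metrics: pd.DataFrame, thresholds: QCThresholds = QCThresholds()) -> np.ndarray:
    """Boolean keep-mask over cells.

    A cell is removed iff ``mito_fraction > max_mito`` or ``n_genes``
    falls strictly outside ``[min_genes, max_genes]`` or ``n_umis``
    strictly outside ``[min_umis, max_umis]``. Idempotent by construction.
    """
    t = thresholds
    bad = (
        (metrics["mito_fraction"].to_numpy() > t.max_mito)
        | (metrics["n_genes"].to_numpy() < t.min_genes)
        | (metrics["n_genes"].to_numpy() > t.max_genes)
        | (metrics["n_umis"].to_numpy() < t.min_umis)
        | (metrics["n_umis"].to_numpy() > t.max_umis)
    )
    return ~bad


def downsample_reads_per_cell(
    adata: ad.AnnData, target: int = 20_000, seed: int = 0
) -> ad.AnnData:
    """Fix every cell's total counts at ``target`` by hypergeometric subsampling.

    Cells whose total is below ``target`` are discarded; cells exactly at
    ``target`` pass through unchanged; cells above are subsampled without
    replacement so that the retained per-gene counts sum to exactly
    ``target`` and never exceed the originals. Seed-deterministic.
    """
    if target <= 0:
        raise ValueError("target must be a positive integer")
    X = _dense_counts(adata).astype(np.int64)
    if np.any(X < 0) or not np.allclose(X, np.round(X)):
        raise ValueError("counts must be non-negative integers")
    totals = X.sum(axis=1)
    keep = totals >= target
    X = X[keep]
    rng = np.random.default_rng(seed)
    out = np.empty_like(X)
    for i, row in enumerate(X):
        tot = row.sum()
        if tot == target:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, target, method="marginals")
    result = ad.AnnData(
        X=out,
        obs=adata.obs.iloc[np.flatnonzero(keep)].copy(),
        var=adata.var.copy(),
    )
    return result
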