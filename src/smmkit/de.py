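"""Patient-balanced Wilcoxon differential expression and the MHC-I score.

Comparing tumor cells between progressors and non-progressors is
confounded by unequal patient cell counts; the analysis therefore draws a
balanced subsample — a per-patient cell quota per group so each group
contributes roughly the same total and each patient the same share — and
runs a per-gene two-sided Wilcoxon rank-sum test across the selected
cells, with Benjamini-Hochberg correction. Effect sizes reported are the
log2 fold change of group means (pseudocount 1) and the rank AUC. The
MHC class I score is the per-cell mean of log1p depth-normalized
expression over HLA-A, HLA-B, HLA-F, HLA-E and B2M.

Counts are expected depth-normalized upstream, e.g. by
:func:`smmkit.qc.downsample_reads_per_cell`; rank tests run on the counts
directly, log1p normalization is applied only for the score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BalanceSpec",
    "MHC1_GENES",
    "draw_balanced_subsample",
    "wilcoxon_bh_de",
    "mhc1_score",
    "leave_one_patient_out",
]

MHC1_GENES = ("HLA-A", "HLA-B", "HLA-F", "HLA-E", "B2M")


@dataclass(frozen=True)
class BalanceSpec:
    """Per-patient cell quotas by group.

    ``per_patient_quota`` maps group label -> cells sampled per patient of
    that group; a patient with fewer cells contributes all of them.
    """

    per_patient_quota: Mapping[str, int]
    seed: int = 0

    def __post_init__(self) -> None:
        if any(q < 1 for q in self.per_patient_quota.values()):
            raise ValueError("quotas must be >= 1")


def draw_balanced_subsample(
    patients: Sequence[str] | np.ndarray,
    groups: Sequence[str] | np.ndarray,
    spec: BalanceSpec,
) -> np.ndarray:
    """Indices of a patient-balanced cell subsample.

    Per patient, ``min(quota, available)`` cells are drawn without
    replacement, where the quota is the group's per-patient quota, so a
    patient with fewer cells than the quota contributes all of them. The
    draw is seed-deterministic and never selects a cell twice.
    """
    patients = np.asarray(patients)
    groups = np.asarray(groups)
    if patients.shape != groups.shape:
        raise ValueError("patients and groups must align")
    for g in spec.per_patient_quota:
        if not np.any(groups == g):
            raise ValueError(f"group {g!r} has no cells")
    rng = np.random.default_rng(spec.seed)
    selected = []
    df = pd.DataFrame({"patient": patients, "group": groups})
    for (patient, group), sub in df.groupby(["patient", "group"], sort=True):
        if group not in spec.per_patient_quota:
            continue
        quota = spec.per_patient_quota[group]
        idx = sub.index.to_numpy()
        if len(idx) > quota:
            idx = rng.choice(idx, size=quota, replace=False)
        selected.append(np.sort(idx))
    if not selected:
        raise ValueError("no cells selected; check group labels and quotas")
    return np.concatenate(selected)


def wilcoxon_bh_de(
    adata: ad.AnnData,
    groups: Sequence[str] | np.ndarray,
    group_a: Optional[str] = None,
    min_expressing_fraction: float = 0.01,
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum DE with BH correction.

    Genes expressed in fewer than ``min_expressing_fraction`` of the
    tested cells are excluded (listed in ``.attrs["excluded_genes"]``).
    ``log2fc`` is ``log2((mean_a + 1) / (mean_b + 1))`` and ``auc`` the
    rank AUC of group A over group B, where A is ``group_a`` (default:
    first label in sorted order).

    Returns a frame with ``gene``, ``p``, ``q``, ``log2fc``, ``auc``.
    """
    groups = np.asarray(groups)
    labels = sorted(pd.unique(pd.Series(groups)))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    a_label = group_a if group_a is not None else labels[0]
    if a_label not in labels:
        raise ValueError(f"group_a={a_label!r} not among {labels}")
    b_label = [l for l in labels if l != a_label][0]
    mask_a = groups == a_label
    mask_b = groups == b_label
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("each group needs >= 2 cells")
    X = adata.X
    X = np.asarray(X.toarray() if sparse.issparse(X) else X, dtype=float)
    expr_frac = (X > 0).mean(axis=0)
    tested = expr_frac >= min_expressing_fraction
    excluded = list(adata.var_names[~tested])
    Xa, Xb = X[mask_a][:, tested], X[mask_b][:, tested]
    res = stats.mannwhitneyu(Xa, Xb, axis=0, alternative="two-sided", method="asymptotic")
    p = np.atleast_1d(res.pvalue)
    u = np.atleast_1d(res.statistic)
    auc = u / (mask_a.sum() * mask_b.sum())
    q = multipletests(p, method="fdr_bh")[1]
    log2fc = np.log2((Xa.mean(axis=0) + 1.0) / (Xb.mean(axis=0) + 1.0))
    out = pd.DataFrame(
        {"gene": adata.var_names[tested], "p": p, "q": q,
         "log2fc": log2fc, "auc": auc}
    ).reset_index(drop=True)
    out.attrs["excluded_genes"] = excluded
    out.attrs["group_a"] = a_label
    out.attrs["group_b"] = b_label
    return out


def mhc1_score(
    adata: ad.AnnData,
    gene_set: Sequence[str] = MHC1_GENES,
    patients: Optional[Sequence[str]] = None,
    target_sum: float = 1e4,
) -> pd.Series | tuple[pd.Series, pd.Series]:
    """MHC class I score: per-cell mean log1p depth-normalized expression.

    Counts are scaled per cell to ``target_sum`` total, log1p-transformed,
    and averaged over the gene set. Missing genes warn and shrink the set.
    When ``patients`` is given, per-patient mean scores are also returned.
    """
    present = [g for g in gene_set if g in adata.var_names]
    absent = set(gene_set) - set(present)
    if absent:
        warnings.warn(f"score genes absent from panel: {sorted(absent)}")
    if not present:
        raise ValueError("no genes of the score set present in the matrix")
    X = adata.X
    X = np.asarray(X.toarray() if sparse.issparse(X) else X, dtype=float)
    totals = X.sum(axis=1)
    scale = np.where(totals > 0, target_sum / np.maximum(totals, 1e-12), 0.0)
    sub = X[:, [adata.var_names.get_loc(g) for g in present]]
    score = np.log1p(sub * scale[:, None]).mean(axis=1)
    per_cell = pd.Series(score, index=adata.obs_names, name="mhc1_score")
    if patients is None:
        return per_cell
    per_patient = per_cell.groupby(np.asarray(patients)).mean()
    return per_cell, per_patient


def leave_one_patient_out(
    adata: ad.AnnData,
    patients: Sequence[str] | np.ndarray,
    groups: Sequence[str] | np.ndarray,
    spec: BalanceSpec,
    leave_out: str,
    loo_quota: Optional[Mapping[str, int]] = None,
    **de_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Leave-one-patient-out stability harness for the balanced DE.

    Runs the balanced subsample + Wilcoxon DE twice — on the full cohort
    and with ``leave_out`` removed (optionally with rebalanced quotas
    ``loo_quota``) — and reports both DE tables plus the Spearman rank
    correlation of their shared genes' p-values, leaving interpretation
    of "no difference" to the user.
    """
    patients = np.asarray(patients)
    groups = np.asarray(groups)
    full_idx = draw_balanced_subsample(patients, groups, spec)
    full = wilcoxon_bh_de(adata[full_idx], groups[full_idx], **de_kwargs)
    keep = patients != leave_out
    if keep.all():
        raise ValueError(f"patient {leave_out!r} not found")
    loo_spec = BalanceSpec(loo_quota or spec.per_patient_quota, seed=spec.seed)
    loo_idx = draw_balanced_subsample(patients[keep], groups[keep], loo_spec)
    sub = adata[np.flatnonzero(keep)]
    loo = wilcoxon_bh_de(sub[loo_idx], groups[keep][loo_idx], **de_kwargs)
    merged = full.merge(loo, on="gene", suffixes=("_full", "_loo"))
    rho = float(stats.spearmanr(merged["p_full"], merged["p_loo"]).statistic)
    return full, loo, rho
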