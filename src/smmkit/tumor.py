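"""Receptor-chain resolution, plasma-cell gating, and malignant-cell calling.

Malignant plasma cells in myeloma precursor samples are identified by
B-cell receptor (BCR) clonality: within each patient, plasma cells are
gated on lineage markers, and the largest BCR clonotype among them is
called the malignant clone when it dominates the clonotyped plasma-cell
pool. IgH-translocation candidates are flagged from marker-gene
overexpression in the called tumor cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "PlasmaGateConfig",
    "TranslocationConfig",
    "IsotypeMismatchWarning",
    "select_contig_chains",
    "gate_plasma_cells",
    "call_malignant_cells",
    "flag_translocation_markers",
]

DEFAULT_PLASMA_MARKERS = ("SDC1", "CD38", "XBP1", "PRDM1", "IRF4", "TNFRSF17")

#: translocation -> marker gene overexpressed under that rearrangement
DEFAULT_TRANSLOCATION_MARKERS = {
    "t(11;14)": "CCND1",
    "t(4;14)": "NSD2",
    "t(14;16)": "MAF",
}


class IsotypeMismatchWarning(UserWarning):
    """Dominant-clone isotype disagrees with the clinically detected isotype."""


@dataclass(frozen=True)
class PlasmaGateConfig:
    marker_genes: Sequence[str] = DEFAULT_PLASMA_MARKERS
    min_markers_detected: int = 2

    def __post_init__(self) -> None:
        if not self.marker_genes:
            raise ValueError("marker gene panel must be non-empty")


@dataclass(frozen=True)
class TranslocationConfig:
    """Flag a translocation when its marker gene is expressed in at least
    ``min_expressing_fraction`` of a patient's tumor cells AND the
    patient's mean expression exceeds the cohort baseline (mean over tumor
    cells of patients failing the fraction criterion) by ``min_fold``."""

    markers: dict = field(default_factory=lambda: dict(DEFAULT_TRANSLOCATION_MARKERS))
    min_expressing_fraction: float = 0.5
    min_fold: float = 4.0


def _dense(X) -> np.ndarray:
    return np.asarray(X.toarray() if sparse.issparse(X) else X)


def select_contig_chains(contigs: pd.DataFrame) -> pd.DataFrame:
    """Resolve each cell barcode to at most two receptor chains.

    Within a barcode and chain locus the single contig with most UMIs is
    kept; across loci the top two chains by UMI count are kept. Ties break
    by read count, then lexicographically by (chain, cdr3), so the result
    is invariant to input row order.
    """
    required = {"barcode", "chain", "cdr3", "umis", "reads"}
    missing = required - set(contigs.columns)
    if missing:
        raise ValueError(f"contig table missing columns: {sorted(missing)}")
    df = contigs.sort_values(
        by=["barcode", "umis", "reads", "chain", "cdr3"],
        ascending=[True, False, False, True, True],
        kind="mergesort",
    )
    best_per_locus = df.drop_duplicates(subset=["barcode", "chain"], keep="first")
    top_two = best_per_locus.groupby("barcode", sort=True).head(2)
    return top_two.reset_index(drop=True)


def gate_plasma_cells(
    adata: ad.AnnData, cfg: PlasmaGateConfig = PlasmaGateConfig()
) -> np.ndarray:
    """Boolean plasma-cell mask: >= ``min_markers_detected`` lineage
    markers with nonzero counts. Missing markers warn and shrink the panel."""
    present = [g for g in cfg.marker_genes if g in adata.var_names]
    absent = set(cfg.marker_genes) - set(present)
    if absent:
        warnings.warn(f"plasma markers absent from panel: {sorted(absent)}")
    if not present:
        raise ValueError("no plasma marker genes present in the matrix")
    X = _dense(adata[:, present].X)
    return (X > 0).sum(axis=1) >= cfg.min_markers_detected


def call_malignant_cells(
    plasma_mask: np.ndarray,
    bcr: pd.DataFrame,
    patients: pd.Series | np.ndarray,
    barcodes: Optional[Sequence[str]] = None,
    dominance_threshold: float = 0.20,
    clinical_isotype: Optional[dict] = None,
) -> pd.DataFrame:
    """Label cells tumor / normal / unassigned from BCR clonality.

    Per patient, the clonotype with the largest cell count among plasma
    cells is the malignant clone iff its frequency among clonotyped plasma
    cells reaches ``dominance_threshold``; its members are ``tumor``,
    other clonotyped plasma cells ``normal``, plasma cells without a BCR
    clonotype ``unassigned``. Non-plasma cells are labeled ``""``.

    Parameters
    ----------
    plasma_mask : boolean plasma gate over cells.
    bcr : resolved BCR contig table with ``barcode``, ``raw_clonotype_id``
        and (optionally) ``c_gene`` holding the heavy-chain isotype.
    patients : per-cell patient label, aligned with ``plasma_mask``.
    barcodes : per-cell barcodes; defaults to ``patients``' index.
    clinical_isotype : optional map patient -> serum-IFE isotype; a
        mismatch with the dominant clone's isotype raises
        :class:`IsotypeMismatchWarning`.

    Returns
    -------
    DataFrame indexed by barcode with ``patient``, ``label`` and
    ``clonotype`` columns, plus per-patient call info in ``.attrs["calls"]``.
    """
    patients = pd.Series(np.asarray(patients))
    if barcodes is None:
        raise ValueError("per-cell barcodes are required")
    barcodes = pd.Index(barcodes)
    plasma_mask = np.asarray(plasma_mask, dtype=bool)
    if not (len(barcodes) == len(patients) == len(plasma_mask)):
        raise ValueError("plasma_mask, patients and barcodes must align")

    clono_by_bc = (
        bcr[bcr["chain"] == "IGH"] if "chain" in bcr.columns else bcr
    ).drop_duplicates("barcode").set_index("barcode")
    labels = pd.DataFrame(
        {"patient": patients.to_numpy(), "label": "", "clonotype": pd.NA},
        index=barcodes,
    )
    calls = {}
    plasma_bcs = barcodes[plasma_mask]
    if len(plasma_bcs) == 0 or not plasma_bcs.isin(clono_by_bc.index).any():
        raise ValueError("no clonotyped plasma cells")
    for patient, bc_group in labels.loc[plasma_bcs].groupby("patient"):
        bcs = bc_group.index
        clonod = bcs[bcs.isin(clono_by_bc.index)]
        labels.loc[bcs, "label"] = "unassigned"
        if len(clonod) == 0:
            calls[patient] = {"clone": None, "dominant": False, "isotype": None,
                              "frequency": np.nan}
            continue
        clones = clono_by_bc.loc[clonod, "raw_clonotype_id"]
        labels.loc[clonod, "clonotype"] = clones.to_numpy()
        counts = clones.value_counts()
        top_clone, top_n = counts.index[0], int(counts.iloc[0])
        freq = top_n / len(clonod)
        dominant = freq >= dominance_threshold
        isotype = None
        if "c_gene" in clono_by_bc.columns:
            iso_counts = clono_by_bc.loc[clonod, "c_gene"][clones == top_clone]
            if len(iso_counts):
                isotype = iso_counts.mode().iloc[0]
        if dominant:
            member = clones == top_clone
            labels.loc[clonod[member], "label"] = "tumor"
            labels.loc[clonod[~member], "label"] = "normal"
            if clinical_isotype and patient in clinical_isotype and isotype is not None:
                if clinical_isotype[patient] != isotype:
                    warnings.warn(
                        f"patient {patient}: dominant clone isotype {isotype} != "
                        f"clinical {clinical_isotype[patient]}",
                        IsotypeMismatchWarning,
                    )
        else:
            labels.loc[clonod, "label"] = "normal"
        calls[patient] = {"clone": top_clone if dominant else None,
                          "dominant": dominant, "isotype": isotype,
                          "frequency": freq}
    labels.attrs["calls"] = calls
    return labels


def flag_translocation_markers(
    adata: ad.AnnData,
    tumor_mask: np.ndarray,
    patients: pd.Series | np.ndarray,
    cfg: TranslocationConfig = TranslocationConfig(),
) -> pd.DataFrame:
    """Per-patient IgH-translocation flags from marker-gene expression.

    For each translocation marker (default CCND1 / NSD2 / MAF), a patient
    is flagged when the marker is expressed in at least
    ``min_expressing_fraction`` of their tumor cells and the patient's
    mean tumor-cell expression is at least ``min_fold`` times the cohort
    baseline (mean over tumor cells of patients failing the fraction
    criterion; the smallest patient mean if every patient passes).
    Markers absent from the panel warn and yield NA flags. The underlying
    statistics are returned so users can re-threshold.
    """
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    patients = pd.Series(np.asarray(patients))
    if tumor_mask.sum() == 0:
        raise ValueError("no tumor cells identified")
    rows = []
    tumor_patients = patients[tumor_mask].reset_index(drop=True)
    for transloc, gene in cfg.markers.items():
        if gene not in adata.var_names:
            warnings.warn(f"marker {gene} absent; {transloc} flag undetermined")
            for patient in tumor_patients.unique():
                rows.append({"patient": patient, "translocation": transloc,
                             "marker": gene, "expressing_fraction": np.nan,
                             "mean_expression": np.nan, "fold_vs_baseline": np.nan,
                             "flag": pd.NA})
            continue
        expr = _dense(adata[tumor_mask, gene].X).ravel()
        stats = (
            pd.DataFrame({"patient": tumor_patients, "expr": expr})
            .groupby("patient")["expr"]
            .agg(expressing_fraction=lambda v: float((v > 0).mean()),
                 mean_expression="mean")
        )
        passing = stats["expressing_fraction"] >= cfg.min_expressing_fraction
        if (~passing).any():
            baseline = float(
                pd.DataFrame({"patient": tumor_patients, "expr": expr})
                .loc[lambda d: d["patient"].isin(stats.index[~passing]), "expr"]
                .mean()
            )
        else:
            baseline = float(stats["mean_expression"].min())
        baseline = max(baseline, 1e-9)
        for patient, row in stats.iterrows():
            fold = row["mean_expression"] / baseline
            rows.append({
                "patient": patient, "translocation": transloc, "marker": gene,
                "expressing_fraction": row["expressing_fraction"],
                "mean_expression": row["mean_expression"],
                "fold_vs_baseline": fold,
                "flag": bool(passing.loc[patient] and fold >= cfg.min_fold),
            })
    return pd.DataFrame(rows)
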