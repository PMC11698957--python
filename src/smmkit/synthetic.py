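"""Synthetic cohorts, lab trajectories, and single-cell repertoire data.

Every pipeline stage in this package is testable without patient-level
data: the generator plants known parameters — group-dependent clonal
expansion, group-dependent effector phenotype fractions within expanded
clones, one dominant malignant BCR clone per patient over a polyclonal
background, a negative-binomial count matrix with a planted MHC class I
shift, QC-outlier cells, and clinical lab trajectories with evolving /
progressing patterns — and emits truth labels alongside, so recovery of
each planted effect can be asserted.

Group-specific parameter vectors are ordered ``(progressor,
non_progressor)`` throughout. All randomness flows from a single
``numpy`` Generator seeded by ``SimConfig.seed``; outputs are
bit-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import anndata as ad
import numpy as np
import pandas as pd

from smmkit import risk

__all__ = ["SimConfig", "ConfigurationError", "generate_cohort",
           "generate_lab_series", "generate_sc_repertoire_dataset"]

GROUPS = ("progressor", "non_progressor")

MHC1_GENES = ("HLA-A", "HLA-B", "HLA-F", "HLA-E", "B2M")
PLASMA_MARKERS = ("SDC1", "CD38", "XBP1", "PRDM1", "IRF4", "TNFRSF17")
TRANSLOC_MARKERS = ("CCND1", "NSD2", "MAF")
TCELL_MARKERS = ("CD3E", "CD8A", "GZMB", "GZMK")
MITO_GENES = ("MT-CO1", "MT-CO2", "MT-ND1", "MT-ND2", "MT-CYB")
NAMED_GENES = MHC1_GENES + PLASMA_MARKERS + TRANSLOC_MARKERS + TCELL_MARKERS + MITO_GENES

RESPONSE_LEVELS = ("CR", "VGPR", "PR", "SD")

AA_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Planted parameters for the synthetic study.

    Group-valued fields are ``(progressor, non_progressor)`` pairs.

    Key knobs: ``clone_concentration`` is the symmetric-Dirichlet
    concentration over ``n_clonotypes`` potential T-cell clonotypes per
    patient (small = oligoclonal / expanded, large = polyclonal);
    ``mhc1_logfc`` is the log2 shift planted on MHC class I genes in
    non-progressor tumor cells; ``gzmb_frac_expanded`` the probability a
    cell of an expanded clone carries the GZMB+ effector phenotype;
    ``hazard`` the exponential event rate in months^-1, censored at
    ``censor_time`` months.
    """

    seed: int = 0
    n_patients_per_group: int = 3
    n_genes: int = 600
    cells_per_patient: int = 400
    plasma_frac: float = 0.5
    mean_depth: float = 2000.0
    nb_dispersion: float = 0.5
    patient_sigma: float = 0.3
    patient_gene_sigma: float = 0.0
    mhc1_logfc: float = 1.0
    clone_concentration: tuple[float, float] = (0.1, 1.0)
    n_clonotypes: int = 200
    gzmb_frac_expanded: tuple[float, float] = (0.3, 0.7)
    gzmb_frac_background: float = 0.5
    dominant_bcr_frac: float = 0.8
    n_bcr_background_clones: int = 20
    qc_outlier_frac: float = 0.05
    hazard: tuple[float, float] = (0.02, 0.005)
    censor_time: float = 60.0
    response_probs: tuple[float, float, float, float] = (0.31, 0.15, 0.47, 0.07)
    lab_noise_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.n_patients_per_group < 1 or self.cells_per_patient < 1 or self.n_genes < 1:
            raise ConfigurationError("sizes must be positive")
        if self.n_genes < len(NAMED_GENES):
            raise ConfigurationError(
                f"n_genes must be >= {len(NAMED_GENES)} to hold the named gene panel "
                "(MHC class I, plasma, translocation, T-cell and mitochondrial markers)"
            )
        if not 0.0 <= self.plasma_frac <= 1.0:
            raise ConfigurationError("plasma_frac must lie in [0, 1]")
        if not 0.0 <= self.gzmb_frac_background <= 1.0:
            raise ConfigurationError("gzmb_frac_background must lie in [0, 1]")
        if not 0.0 <= self.qc_outlier_frac < 1.0:
            raise ConfigurationError("qc_outlier_frac must lie in [0, 1)")
        if not 0.0 < self.dominant_bcr_frac <= 1.0:
            raise ConfigurationError("dominant_bcr_frac must lie in (0, 1]")
        for pair_name in ("clone_concentration", "gzmb_frac_expanded", "hazard"):
            pair = getattr(self, pair_name)
            if len(pair) != len(GROUPS):
                raise ConfigurationError(f"{pair_name} must have one value per group")
        if any(c <= 0 for c in self.clone_concentration):
            raise ConfigurationError("clone_concentration values must be positive")
        if any(not 0.0 <= f <= 1.0 for f in self.gzmb_frac_expanded):
            raise ConfigurationError("gzmb_frac_expanded values must lie in [0, 1]")
        if any(h < 0 for h in self.hazard):
            raise ConfigurationError("hazard rates must be >= 0")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if abs(sum(self.response_probs) - 1.0) > 1e-9:
            raise ConfigurationError("response_probs must sum to 1")


def gene_panel(n_genes: int) -> list[str]:
    """Gene names: the fixed marker panel followed by numbered fillers."""
    fillers = [f"GENE{i:04d}" for i in range(n_genes - len(NAMED_GENES))]
    return list(NAMED_GENES) + fillers


def sample_negative_binomial(rng: np.random.Generator, mu: np.ndarray,
                             dispersion: float) -> np.ndarray:
    """NB draws parameterized by mean and dispersion (var = mu + dispersion * mu^2)."""
    mu = np.asarray(mu, dtype=float)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mu)
    return rng.negative_binomial(size_param, np.clip(p, 1e-12, 1.0))


# ---------------------------------------------------------------------------
# cohort


def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """One row per patient: group, 20/2/20 inputs, best response, event time.

    Event times are Exponential(hazard) in months, right-censored at
    ``censor_time`` (a zero hazard censors every patient). Best response
    is multinomial over ``RESPONSE_LEVELS`` with ``response_probs``.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    pid = 0
    for gi, group in enumerate(GROUPS):
        hazard = config.hazard[gi]
        for _ in range(config.n_patients_per_group):
            pid += 1
            bmpc = float(np.round(rng.uniform(10, 55), 1))
            m_protein = float(np.round(rng.lognormal(np.log(2.0), 0.4), 2))
            flc_ratio = float(np.round(rng.lognormal(np.log(15.0), 0.8), 2))
            response = RESPONSE_LEVELS[rng.choice(4, p=config.response_probs)]
            if hazard > 0:
                raw_time = rng.exponential(1.0 / hazard)
            else:
                raw_time = np.inf
            event = int(raw_time <= config.censor_time)
            time = float(min(raw_time, config.censor_time))
            rows.append({
                "patient": f"P{pid:02d}", "group": group, "bmpc": bmpc,
                "m_protein": m_protein, "flc_ratio": flc_ratio,
                "best_response": response, "time_months": round(time, 3),
                "event": event,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# lab trajectories

Pattern = Literal["stable", "evolving", "progressing"]

_BASE_M = 2.0  # g/dL
_BASE_IFLC = 150.0  # mg/L
_BASE_UFLC = 15.0  # mg/L


def _pattern_trend(pattern: Pattern, times: np.ndarray) -> np.ndarray:
    """Noise-free M-protein trend (g/dL) at the given day grid."""
    m = np.full(times.shape, _BASE_M)
    if pattern == "evolving":
        pre = times <= 0
        # 30% ramp over the 6 pre-screening months; flat afterwards
        m[pre] = _BASE_M * (1.0 + 0.30 * (times[pre] - times[pre][0])
                            / (0 - times[pre][0]))
        m[~pre] = m[pre][-1]
    elif pattern == "progressing":
        post = times > 0
        tp = times[post]
        # post-baseline dip to a nadir then a steep rebound: >= 25% above
        # the nadir and >= 0.5 g/dL absolute by the end of follow-up
        dip = _BASE_M * (1.0 - 0.25 * np.clip(tp / 90.0, 0.0, 1.0))
        rebound = np.clip((tp - 90.0) / 270.0, 0.0, 1.0)
        m[post] = dip + rebound * (_BASE_M * 1.5 - dip)
    return m


def _series_ok(pattern: Pattern, df: pd.DataFrame) -> bool:
    evolving = risk.detect_evolving_pattern(df)
    progression = risk.detect_biochemical_progression(df)
    if pattern == "stable":
        return (not evolving) and progression is None
    if pattern == "evolving":
        return evolving
    return progression is not None


def generate_lab_series(config: SimConfig, pattern: Pattern,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Monthly serum series from 6 months pre-screening to 12 months after.

    Columns: ``time_days`` (negative = before screening), ``m_protein``
    (g/dL), ``involved_flc`` / ``uninvolved_flc`` (mg/L). Trends are
    piecewise-linear with multiplicative log-normal noise (CV
    ``lab_noise_cv``, clipped at +/- 2 sigma); the residual noise is
    halved until the pattern's defining rule holds, so the guarantee
    (``evolving`` detected, ``progressing`` has an onset, ``stable``
    triggers neither) is exact rather than probabilistic.
    """
    if pattern not in ("stable", "evolving", "progressing"):
        raise ValueError(f"unknown pattern: {pattern!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    times = np.arange(-180, 361, 30, dtype=float)
    trend = _pattern_trend(pattern, times)
    sigma = config.lab_noise_cv
    log_noise = np.clip(rng.normal(0.0, sigma, size=times.shape), -2 * sigma, 2 * sigma)
    for _ in range(60):
        df = pd.DataFrame({
            "time_days": times,
            "m_protein": np.round(trend * np.exp(log_noise), 3),
            "involved_flc": np.round(_BASE_IFLC * np.exp(log_noise), 1),
            "uninvolved_flc": np.full(times.shape, _BASE_UFLC),
        })
        if _series_ok(pattern, df):
            return df
        log_noise = log_noise / 2.0
    raise RuntimeError("lab-series repair loop failed to converge")  # pragma: no cover


# ---------------------------------------------------------------------------
# single-cell repertoire dataset


def _random_cdr3(rng: np.random.Generator, length: int = 13) -> str:
    return "C" + "".join(rng.choice(AA_ALPHABET, size=length - 2)) + "F"


def _draw_clonotype_codes(rng: np.random.Generator, n_cells: int,
                          concentration: float, n_clonotypes: int) -> np.ndarray:
    freqs = rng.dirichlet(np.full(n_clonotypes, concentration))
    return rng.choice(n_clonotypes, size=n_cells, p=freqs)


def generate_sc_repertoire_dataset(
    config: SimConfig,
) -> tuple[ad.AnnData, pd.DataFrame, pd.DataFrame]:
    """Counts + TCR contigs + BCR contigs with planted truth labels.

    Per patient, half the cells (``plasma_frac``) are plasma cells whose
    BCR clonotypes contain one dominant malignant clone at frequency
    ``dominant_bcr_frac`` (with a patient-specific isotype) over a
    polyclonal background; the rest are T cells with clonotype frequencies
    from a symmetric Dirichlet at the group's concentration, GZMB+/GZMK+
    phenotypes assigned at group-specific rates within expanded clones,
    and MHC class I genes shifted by ``mhc1_logfc`` in non-progressor
    tumor cells. A ``qc_outlier_frac`` of cells is corrupted to violate at
    least one QC rule. Truth labels for every planted property live in
    ``adata.obs`` (per cell) and ``adata.uns["patient_truth"]`` (per
    patient).

    Returns ``(adata, tcr_contigs, bcr_contigs)`` with cells x genes
    counts and cell-ranger-style contig tables.
    """
    rng = np.random.default_rng(config.seed)
    genes = gene_panel(config.n_genes)
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_per_patient = config.cells_per_patient
    n_plasma = int(round(config.plasma_frac * n_per_patient))
    n_t = n_per_patient - n_plasma

    # gene-wise relative expression, shared across patients; MHC class I
    # genes are constitutively high in plasma cells, so they get a fixed
    # elevated weight rather than a random one
    base_weight = rng.lognormal(0.0, 1.0, size=config.n_genes)
    for g in MHC1_GENES:
        base_weight[gene_idx[g]] = 10.0

    obs_rows, count_blocks, tcr_rows, bcr_rows, patient_truth = [], [], [], [], []
    isotype_choices = ("IGHG1", "IGHG2", "IGHA1", "IGHM")

    pid = 0
    for gi, group in enumerate(GROUPS):
        for pi in range(config.n_patients_per_group):
            pid += 1
            patient = f"P{pid:02d}"
            patient_depth = config.mean_depth * rng.lognormal(0.0, config.patient_sigma)
            gene_effect = (
                rng.lognormal(0.0, config.patient_gene_sigma, size=config.n_genes)
                if config.patient_gene_sigma > 0 else 1.0
            )
            has_t11_14 = pi == 0  # plant CCND1 overexpression in one patient per group
            dominant_isotype = isotype_choices[rng.choice(len(isotype_choices))]

            # ---- per-cell clonotype structure
            # plasma: exact dominant-clone count so the truth label
            # ("dominant clone truly largest") holds by construction
            n_dom = max(1, int(round(config.dominant_bcr_frac * n_plasma)))
            n_bg = n_plasma - n_dom
            bg_codes = rng.choice(config.n_bcr_background_clones, size=n_bg)
            # guard: dominant clone strictly largest
            if n_bg:
                largest_bg = np.bincount(bg_codes).max()
                while largest_bg >= n_dom and n_bg > 0:
                    n_dom += 1
                    n_bg -= 1
                    bg_codes = bg_codes[:n_bg]
                    largest_bg = np.bincount(bg_codes).max() if n_bg else 0
            plasma_clone = np.array(
                [f"{patient}_B00"] * n_dom + [f"{patient}_B{c + 1:02d}" for c in bg_codes]
            )
            perm = rng.permutation(n_plasma)
            plasma_clone = plasma_clone[perm]
            is_tumor = plasma_clone == f"{patient}_B00"

            t_codes = _draw_clonotype_codes(
                rng, n_t, config.clone_concentration[gi], config.n_clonotypes
            )
            t_clone = np.array([f"{patient}_T{c:03d}" for c in t_codes])
            clone_counts = pd.Series(t_clone).value_counts()
            clone_freq = (clone_counts / n_t).to_dict()
            t_expanded = np.array([clone_freq[c] > 0.01 for c in t_clone])
            gzmb_p = np.where(t_expanded, config.gzmb_frac_expanded[gi],
                              config.gzmb_frac_background)
            t_phenotype = np.where(rng.random(n_t) < gzmb_p, "GZMB+", "GZMK+")

            # ---- expression means
            celltype = np.array(["plasma"] * n_plasma + ["t"] * n_t)
            weight = np.tile(base_weight * gene_effect, (n_per_patient, 1))
            plasma_idx = [gene_idx[g] for g in PLASMA_MARKERS]
            tcell_idx = [gene_idx[g] for g in ("CD3E", "CD8A")]
            weight[:n_plasma][:, plasma_idx] *= 20.0
            weight[:n_plasma][:, tcell_idx] *= 0.02
            weight[n_plasma:][:, plasma_idx] *= 0.02
            weight[n_plasma:][:, tcell_idx] *= 20.0
            gzmb_cells = n_plasma + np.flatnonzero(t_phenotype == "GZMB+")
            gzmk_cells = n_plasma + np.flatnonzero(t_phenotype == "GZMK+")
            weight[gzmb_cells, gene_idx["GZMB"]] *= 30.0
            weight[gzmb_cells, gene_idx["GZMK"]] *= 0.1
            weight[gzmk_cells, gene_idx["GZMK"]] *= 30.0
            weight[gzmk_cells, gene_idx["GZMB"]] *= 0.1
            tumor_rows = np.flatnonzero(np.concatenate([is_tumor, np.zeros(n_t, bool)]))
            if group == "non_progressor" and config.mhc1_logfc != 0.0:
                mhc_idx = [gene_idx[g] for g in MHC1_GENES]
                weight[np.ix_(tumor_rows, mhc_idx)] *= 2.0 ** config.mhc1_logfc
            if has_t11_14:
                weight[tumor_rows, gene_idx["CCND1"]] *= 10.0

            mu = weight / weight.sum(axis=1, keepdims=True) * patient_depth
            counts = sample_negative_binomial(rng, mu, config.nb_dispersion)

            # ---- QC outliers
            n_out = int(round(config.qc_outlier_frac * n_per_patient))
            out_cells = rng.choice(n_per_patient, size=n_out, replace=False)
            qc_rule = np.array([""] * n_per_patient, dtype=object)
            mito_idx = [gene_idx[g] for g in MITO_GENES]
            for j, cell in enumerate(out_cells):
                if j % 2 == 0:  # mitochondrial blow-up: mito fraction > 0.15
                    total = counts[cell].sum()
                    counts[cell, mito_idx] += int(np.ceil(0.5 * max(total, 10)))
                    qc_rule[cell] = "high_mito"
                else:  # degraded droplet: < 400 total counts
                    keep = rng.random(config.n_genes) < 100.0 / max(counts[cell].sum(), 1)
                    counts[cell] = np.where(keep, counts[cell], 0)
                    if counts[cell].sum() >= 400:
                        counts[cell] = (counts[cell] * 0).astype(counts.dtype)
                        counts[cell, gene_idx["CD38"]] = 50
                    qc_rule[cell] = "low_umis"
            is_outlier = qc_rule != ""

            # ---- metadata + contigs
            for i in range(n_per_patient):
                bc = f"{patient}-BC{i:04d}"
                obs_rows.append({
                    "barcode": bc, "patient": patient, "group": group,
                    "celltype": celltype[i],
                    "truth_is_tumor": bool(i < n_plasma and is_tumor[i]),
                    "truth_clonotype": (plasma_clone[i] if i < n_plasma
                                        else t_clone[i - n_plasma]),
                    "truth_phenotype": ("" if i < n_plasma
                                        else t_phenotype[i - n_plasma]),
                    "truth_expanded": bool(i >= n_plasma and t_expanded[i - n_plasma]),
                    "truth_qc_outlier": bool(is_outlier[i]),
                    "truth_qc_rule": qc_rule[i],
                })
            count_blocks.append(counts)

            cdr3_cache: dict[tuple[str, str], str] = {}

            def cdr3_for(clone: str, locus: str) -> str:
                key = (clone, locus)
                if key not in cdr3_cache:
                    cdr3_cache[key] = _random_cdr3(rng)
                return cdr3_cache[key]

            for i in range(n_plasma):
                bc = f"{patient}-BC{i:04d}"
                clone = plasma_clone[i]
                iso = dominant_isotype if clone.endswith("B00") else (
                    isotype_choices[rng.choice(len(isotype_choices))]
                )
                umis_h = int(rng.integers(4, 40))
                bcr_rows.append({"barcode": bc, "chain": "IGH",
                                 "cdr3": cdr3_for(clone, "IGH"), "umis": umis_h,
                                 "reads": umis_h * 40, "raw_clonotype_id": clone,
                                 "c_gene": iso})
                umis_l = int(rng.integers(4, 40))
                bcr_rows.append({"barcode": bc, "chain": "IGK",
                                 "cdr3": cdr3_for(clone, "IGK"), "umis": umis_l,
                                 "reads": umis_l * 40, "raw_clonotype_id": clone,
                                 "c_gene": "IGKC"})
            for i in range(n_t):
                bc = f"{patient}-BC{n_plasma + i:04d}"
                clone = t_clone[i]
                for locus, cg in (("TRA", "TRAC"), ("TRB", "TRBC2")):
                    umis = int(rng.integers(2, 30))
                    tcr_rows.append({"barcode": bc, "chain": locus,
                                     "cdr3": cdr3_for(clone, locus), "umis": umis,
                                     "reads": umis * 40, "raw_clonotype_id": clone,
                                     "c_gene": cg})

            patient_truth.append({
                "patient": patient, "group": group,
                "dominant_bcr_clone": f"{patient}_B00",
                "clinical_isotype": dominant_isotype,
                "truth_t11_14": has_t11_14,
                "truth_mhc1_shifted": group == "non_progressor"
                and config.mhc1_logfc != 0.0,
            })

    obs = pd.DataFrame(obs_rows).set_index("barcode")
    adata = ad.AnnData(X=np.vstack(count_blocks).astype(np.int64), obs=obs)
    adata.var_names = genes
    adata.uns["patient_truth"] = pd.DataFrame(patient_truth)
    tcr = pd.DataFrame(tcr_rows)
    bcr = pd.DataFrame(bcr_rows)
    return adata, tcr, bcr
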