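# smmkit

Statistical toolkit for single-arm interception trials in smoldering
multiple myeloma (SMM) and their single-cell immune correlatives.

High-risk SMM is an asymptomatic plasma-cell condition with a high chance
of progressing to overt myeloma. Trials that treat it early need three
kinds of machinery, all provided here as a tested, reusable library:

1. **Exact trial statistics** (`smmkit.trial`) — the single-stage exact
   binomial design (find the smallest *n* and critical value *r* with
   P(X ≥ r | n, p₀) ≤ α and P(X ≥ r | n, p₁) ≥ 1 − β), exact binomial
   tests and Clopper-Pearson intervals for response tables, Fisher's
   exact test (probability-mass two-sided rule), the Cochran-Armitage
   trend test over ordered risk groups, and Kaplan-Meier curves with
   log-rank comparison and reverse-KM median follow-up.
2. **Clinical rule engines** (`smmkit.risk`) — the IMWG 20/2/20 risk
   model (FLC ratio > 20, M protein > 2 g/dL, bone-marrow plasma cells
   > 20%; ≥ 2 factors = high risk), Mayo 2008 factors, evolving-pattern
   detection (≥ 10% rise of M protein or involved FLC in the 6 months
   before screening), IMWG-style biochemical-progression onset (≥ 25%
   rise from nadir with absolute minimums), and serum-based response
   depth (sCR/CR/VGPR/PR/MR/SD).
3. **Single-cell correlatives** — droplet QC and fixed-depth count
   downsampling (`smmkit.qc`); receptor-chain resolution, plasma-cell
   gating, malignant-cell calling from the dominant BCR clone, and
   IgH-translocation flags from marker genes (`smmkit.tumor`);
   downsampled TCR clone-size estimation with size categories
   (rare ≤ 1% < small < 5% ≤ medium < 10% ≤ large), category
   composition, and bootstrap group tests over patients
   (`smmkit.repertoire`); patient-balanced Wilcoxon rank-sum
   differential expression with Benjamini-Hochberg correction and the
   MHC class I score (mean log1p depth-normalized expression of
   *HLA-A, HLA-B, HLA-F, HLA-E, B2M*) (`smmkit.de`).

`smmkit.synthetic` generates full synthetic studies — cohort tables, lab
trajectories, negative-binomial count matrices, and TCR/BCR contig
tables — with known planted parameters (clonal expansion per group, a
dominant malignant BCR clone per patient, an MHC-I shift in
non-progressor tumor cells, QC outliers) and truth labels, so every
stage is testable without access to patient-level data.

## Worked example

```python
from smmkit import trial, de, qc, synthetic

# exact single-stage design: 50% vs 70% progression-free, 5%/10% errors
design = trial.design_single_stage(
    trial.DesignSpec(p0=0.50, p1=0.70, alpha=0.05, beta=0.10))
print(f"design: n={design.n}, r={design.r}, "
      f"alpha={design.attained_alpha:.4f}, power={design.attained_power:.4f}")

lo, hi = trial.clopper_pearson_ci(25, 55)
print(f"VGPR-or-better 25/55: {25/55:.0%} (95% CI {lo:.0%}-{hi:.0%})")

odds, p = trial.fisher_exact_test(9, 20, 16, 10)
print(f"deep response, evolving vs non-evolving: OR={odds:.2f}, p={p:.3f}")

# synthetic single-cell study: recover the planted MHC class I shift
cfg = synthetic.SimConfig(seed=7)
adata, tcr, bcr = synthetic.generate_sc_repertoire_dataset(cfg)
keep = qc.filter_cells_qc(qc.compute_qc_metrics(adata))
tumor_cells = adata[keep & adata.obs["truth_is_tumor"].to_numpy()]
depth_fixed = qc.downsample_reads_per_cell(tumor_cells, target=500, seed=7)
spec = de.BalanceSpec({"progressor": 150, "non_progressor": 150}, seed=7)
idx = de.draw_balanced_subsample(depth_fixed.obs["patient"].to_numpy(),
                                 depth_fixed.obs["group"].to_numpy(), spec)
sub = depth_fixed[idx]
table = de.wilcoxon_bh_de(sub, sub.obs["group"].to_numpy(),
                          group_a="non_progressor")
print(table[table["gene"].isin(de.MHC1_GENES)][["gene", "q", "log2fc"]]
      .round(3).to_string(index=False))
```

Output:

```
design: n=53, r=33, alpha=0.0492, power=0.9138
VGPR-or-better 25/55: 45% (95% CI 32%-59%)
deep response, evolving vs non-evolving: OR=0.28, p=0.032
 gene   q  log2fc
HLA-A 0.0   0.804
HLA-B 0.0   0.742
HLA-F 0.0   0.804
HLA-E 0.0   0.851
  B2M 0.0   0.890
```

Reading the numbers: a trial enrolling 53 patients rejects a 50%
progression-free null when ≥ 33 remain progression-free, with one-sided
type-I error 4.9% and power 91.4% at the 70% alternative. Of 55
patients, 25 deep responders give 45% (exact 95% CI 32–59%). The 2×2
evolving-by-response table yields p = 0.032: patients with an evolving
pre-treatment pattern reach deep responses less often. In the synthetic
study, all five MHC class I genes are recovered at q ≈ 0 with a
positive log2 fold change in non-progressor tumor cells, matching the
planted one-log2 shift.

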