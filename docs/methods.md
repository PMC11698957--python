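# Methods

This note records the models and procedures smmkit implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Exact trial statistics

**Single-stage binomial design.** For null progression-free rate p₀,
alternative p₁, one-sided type-I bound α and type-II bound β, the search
returns the smallest n admitting a critical value r with exact tails
P(X ≥ r | n, p₀) ≤ α and P(X ≥ r | n, p₁) ≥ 1 − β; for each n the
smallest α-feasible r is taken because power is decreasing in r. Only
exact binomial tails are used — no normal approximation — so the
attained errors reported alongside (n, r) are exact. α is interpreted
one-sided, the natural reading for a one-arm design; a two-sided
interpretation makes the standard 50%-vs-70% design (n = 53, r = 33)
unreachable.

**Exact binomial test / Clopper-Pearson interval.** Both delegate to
`scipy.stats.binomtest`; the interval inverts the binomial tails at
(1 − conf)/2 per side, with closed endpoints 0 (x = 0) and 1 (x = n).

**Fisher's exact test.** Two-sided p by the probability-mass rule: the
sum over all tables with the observed margins whose hypergeometric
probability does not exceed the observed table's (scipy's convention).
The reported odds ratio is the sample odds ratio ad/bc, infinite when
bc = 0. The all-zero table is a domain error.

**Cochran-Armitage trend.** Asymptotic score test with equally spaced
default scores and no continuity correction; two-sided normal p. A
zero-variance table (all successes or all failures) returns p = 1 with
a degeneracy flag rather than NaN. Implemented directly (statsmodels
exposes no dedicated API); the two-group case is cross-checked against
the Pearson chi-square identity z² = χ² in the tests.

**Survival.** Kaplan-Meier estimation, the unweighted log-rank test and
the reverse-KM median (indicators swapped, so censoring is the event)
are backed by lifelines. Curve confidence bands use the exponential
Greenwood (log-log) transform — lifelines' default — because the
log-log band respects [0, 1]. The median is the earliest time with
S(t) ≤ 0.5 and is reported as "not reached" (`None`) when the curve
never drops that far. A sample with no events is a degenerate log-rank
comparison and returns p = 1 with a flag; a single group is an error.

## Clinical rule engines

All rules operate on serum quantities: M protein in g/dL, free light
chains in mg/L, bone-marrow plasma cells (BMPC) in percent, time in
days relative to screening.

- **20/2/20**: strict inequalities (FLC ratio > 20, M > 2, BMPC > 20),
  so boundary values do not count; ≥ 2 factors is high risk. **Mayo
  2008**: inclusive cutoffs (BMPC ≥ 10, M ≥ 3, FLC ratio ≥ 8 or
  ≤ 0.125). The two conventions follow how the cutoffs are customarily
  printed.
- **Evolving pattern**: a relative rise of ≥ 10% of M protein *or*
  involved FLC within the 183-day window before screening, comparing
  each value against the running minimum of earlier in-window values.
  Fewer than two in-window measurements is an explicit
  insufficient-data error rather than a silent false.
- **Biochemical progression**: earliest post-baseline time at which M
  protein rises ≥ 25% from its running nadir with an absolute increase
  ≥ 0.5 g/dL, or the involved-minus-uninvolved FLC difference rises
  ≥ 25% from nadir with an absolute increase ≥ 100 mg/L. The absolute
  minimums are the IMWG ones; urine M protein is not modeled.
- **Response depth** is a serum-based simplification: CR requires
  negative immunofixation and BMPC < 5% (sCR additionally a normalized
  FLC ratio); VGPR a ≥ 90% M reduction or unmeasurable M with positive
  immunofixation; PR ≥ 50%; MR ≥ 25%; else SD. Urine and imaging
  components are deliberately out of scope, so depths that depend on
  them are approximated by their serum criteria.

## Single-cell procedures

**QC.** A droplet is removed iff mitochondrial fraction > 0.15, detected
genes < 200 or > 5000, or total counts < 400 or > 50,000; boundary
values are kept. Metrics are computed from the matrix itself, with
mitochondrial genes identified by the "MT-" name prefix (configurable).

**Fixed-depth downsampling.** Cells below the target total are
discarded; cells above it are subsampled *without replacement*
(multivariate hypergeometric, via numpy's generator) to exactly the
target, so every retained cell has an identical total, per-gene counts
never exceed the originals, and the result is seed-deterministic.
"Reads per cell" is operationalized as total counts in the matrix.
Sampling without replacement is chosen because it preserves the
count-sum identity; the pipeline default is QC first, then
downsampling.

**Chain resolution.** Per barcode and locus the contig with most UMIs
is kept; across loci the top two chains by UMIs. Ties break by reads,
then lexicographically by (chain, CDR3), making the output invariant to
input row order.

**Malignant-cell calling.** Plasma cells are gated by ≥ 2 detected
lineage markers (SDC1, CD38, XBP1, PRDM1, IRF4, TNFRSF17). Per patient,
the largest BCR clonotype among gated plasma cells is called malignant
iff its frequency among clonotyped plasma cells reaches a dominance
threshold (default 20%); members are tumor, other clonotyped plasma
cells normal, BCR-less plasma cells unassigned. The dominance threshold
replaces embedding-based separation from normal plasma cells, which is
not reproducible from a text description; 20% prevents spurious calls
in polyclonal marrow while accepting any genuinely expanded clone. A
clinically reported serum isotype can be supplied; disagreement with
the dominant clone's isotype raises a warning rather than vetoing the
call. Translocation flags (CCND1 / NSD2 / MAF for t(11;14) / t(4;14) /
t(14;16)) require the marker expressed in ≥ 50% of a patient's tumor
cells and a ≥ 4-fold mean over the cohort baseline (tumor cells of
patients failing the fraction criterion; the smallest patient mean if
all pass). These thresholds are explicit heuristics; the underlying
statistics are returned so users can re-threshold.

**Clone sizes and composition.** Clone sizes are estimated by drawing
100 cells (without replacement) 100 times, averaging each clone's
proportion of the draw, and categorizing: rare ≤ 1% < small < 5% ≤
medium < 10% ≤ large. The rare boundary is inclusive (≤ 1%); where
descriptions disagree the category definition used here is the
procedural one, and cutpoints are configurable. When a patient has
fewer cells than the sample size, every draw is the full set, and the
code short-circuits to exact empirical proportions (zero Monte Carlo
variance, exactly). Category composition per cell subtype repeats the
downsampling, counts the categories of the *unique clonotypes* observed
in each draw, averages, and renormalizes to sum exactly to 1.

**Bootstrap group test.** Patients — the biological replicate — are
resampled with replacement within each group. The default p-value rule
is a studentized bootstrap (bootstrap-t): the observed mean difference
standardized by its standard error is compared to the resampled
distribution of (d* − d)/se*. The simpler sign-crossing percentile rule
2·min(P(d* ≤ 0), P(d* ≥ 0)) is retained as `method="percentile"`, but
at trial-like group sizes (≈ 6 patients per group) it measured a
type-I error of 0.10–0.14 at nominal 0.05, while the studentized rule
measured 0.02–0.03; the studentized rule is therefore the default. Both
preserve the natural boundary behavior (identical groups → p = 1;
disjoint constant groups → the 1/B floor), and both are floored at
1/B and capped at 1.

**Balanced differential expression.** A per-patient quota per group is
drawn without replacement (patients under quota contribute all cells —
mirroring how a cohort with one small patient sample is handled), then
a per-gene two-sided Wilcoxon rank-sum test with tie correction runs
across the selected cells, with Benjamini-Hochberg q-values over all
tested genes. Genes expressed in < 1% of tested cells are excluded (and
reported) to stabilize rank tests on near-empty genes. Effect sizes are
log2((mean_A + 1)/(mean_B + 1)) and the rank AUC; both are reported
because rank tests carry no canonical effect size. Rank tests run on
the depth-fixed counts directly; log1p normalization (per-cell scaling
to 10,000 counts) is applied only for the MHC class I score. A
leave-one-patient-out harness reruns the procedure without a chosen
patient (optionally with rebalanced quotas) and reports the Spearman
correlation of gene p-values between runs, leaving interpretation to
the user — under a mostly-null panel that correlation is dominated by
null noise, so the meaningful stability check is whether the signal
genes persist.

## The synthetic generator

The generator emulates the features the pipeline is sensitive to, not
transcriptome-wide biology. Defaults (all in `SimConfig`):

| parameter | default | meaning |
|---|---|---|
| n_patients_per_group | 3 | patients per (progressor, non-progressor) group |
| cells_per_patient | 400 | half plasma cells, half T cells |
| n_genes | 600 | named marker panel + numbered fillers |
| mean_depth | 2000 | mean counts per cell |
| nb_dispersion | 0.5 | var = μ + 0.5 μ² per gene |
| patient_sigma | 0.3 | per-patient log-normal depth factor |
| patient_gene_sigma | 0.0 | per-gene × patient effect (see below) |
| mhc1_logfc | 1.0 | log2 MHC-I shift in non-progressor tumor cells |
| clone_concentration | (0.1, 1.0) | Dirichlet concentration (progressor, non-progressor) |
| n_clonotypes | 200 | potential T-cell clonotypes per patient |
| gzmb_frac_expanded | (0.3, 0.7) | P(GZMB+) within expanded clones per group |
| dominant_bcr_frac | 0.8 | malignant-clone share of plasma cells |
| qc_outlier_frac | 0.05 | cells corrupted to violate a QC rule |
| hazard | (0.02, 0.005) mo⁻¹ | exponential event rates, censored at 60 mo |

Counts are negative-binomial per gene with a per-patient scalar depth
factor (log-normal, σ = 0.3). A per-gene × patient random effect is
available (`patient_gene_sigma`) but defaults to 0: balanced
subsampling equalizes patient *contributions* but a cell-level rank
test cannot remove per-gene patient effects, so with 3 patients per
group any nonzero per-gene effect is statistically indistinguishable
from a group effect — a real limitation of cell-level DE at small
cohort sizes that users should keep in mind; with the default of 0 the
generator's null (no planted shift) is a true null for the procedure.
MHC class I genes carry a fixed elevated base weight rather than a
random one because they are constitutively high in plasma cells; a
random weight would make planted-shift recovery depend on a gene
lottery rather than on the method.

T-cell clonotype frequencies are symmetric-Dirichlet draws; the
concentration is the single expansion knob (0.1 gives an oligoclonal,
expanded repertoire; 1.0 a polyclonal one; → ∞ near-uniform
singletons). The dominant BCR clone is constructed with an exact cell
count (adjusted upward in the rare case a background clone would tie),
so the truth label "largest clone" holds by construction. QC outliers
are corrupted cells — mitochondrial blow-up or degraded low-count
droplets — and their truth labels are recorded with the violated rule.
Lab trajectories are piecewise-linear with multiplicative log-normal
noise (CV 5%, clipped at ±2σ); if a noisy draw breaks the pattern's
defining rule (an evolving series must be detected, a stable one must
not, a progressing one must have an onset), the residual noise is
halved until the rule holds, making the generator's guarantee exact
rather than probabilistic.

What the generator does **not** emulate: somatic hypermutation,
realistic gene-gene correlation, doublets and ambient RNA, urine
analytes, imaging, and transcriptome-scale panels. Passing tests
therefore demonstrate correctness of the procedures under a controlled
generative model, not performance on real marrow samples.

## Problem sizes used in tests

The recovery simulations run the full pipeline — QC filter, fixed-depth
downsampling at 500 counts/cell, balanced quota of 150 cells per
patient, Wilcoxon + BH — at the generator defaults above, across 20
seeds. The downsampling target sits well below every patient's typical
depth, mirroring the design in which the fixed-depth cutoff discards
individual poor droplets rather than decimating whole patients; an
earlier scaled pipeline with the target at a quarter of mean depth
showed how a patient falling mostly below the cutoff lets that
patient's private expression markers masquerade as group differences —
confounding by attrition, worth knowing about when choosing a cutoff on
real data. Bootstrap calibration uses 500 null runs of 6 + 6 patients
at 1000 resamples. The exact-statistics checks (design search with
brute-force minimality to n = 60, Fisher enumeration over all 2×2
tables with N ≤ 12, Clopper-Pearson coverage at 10⁴ draws) run in
seconds.

## Known limitations

- The response engine ignores urine and imaging criteria; depths
  requiring them are approximated by serum rules.
- Cell-level rank-sum DE cannot separate per-gene patient effects from
  group effects at few patients per group (see above); pseudobulk or
  mixed models are out of scope.
- Translocation flagging is a marker-gene heuristic, not copy-number
  inference; it reports its underlying statistics for re-thresholding.
- The bootstrap group test assumes exchangeable patients within group;
  with only 2–3 patients per group any resampling test is coarse, and
  the 1/B floor is the smallest attainable p.
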