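# Methods

## The analysis

`ithimmune` implements an integrative bulk-transcriptomics workflow that
links intra-tumoral heterogeneity (ITH) to the tumor immune landscape
and derives immune subtypes with distinct outcomes. The chain is:

1. **Heterogeneity (MATH).** Each tumor's mutant-allele tumor
   heterogeneity score is `100 × MAD / median` of its somatic variant
   allele fractions (VAFs), with MAD the scaled median absolute
   deviation (constant 1.4826). VAFs outside [0.075, 0.75] are excluded
   by default — the conventional window for dropping likely germline or
   copy-number-distorted variants — and samples with fewer than 5
   surviving variants are flagged rather than scored. Tumors are split
   at the cohort median MATH into low- and high-heterogeneity groups
   (ties to LOW, making the split deterministic); with matched normals
   this yields the three ordered groups normal → low-het → high-het.

2. **Pathway activity, two methods.**
   *Group-level weighted relative expression*: for gene *i* and group
   *j*, `E_ij` is the group-mean log2 expression, `r_ij = E_ij /
   mean_j(E_ij)`, and pathway activity is the weighted average
   `p_tj = Σ w_i r_ij / Σ w_i` with `w_i` the reciprocal of the number
   of pathways containing gene *i*. Two identities are enforced by
   construction and tested: `mean_j r_ij = 1` per gene, and
   `min r ≤ p_tj ≤ max r` within a pathway.
   *Per-sample ssGSEA*: genes are ranked within a sample (largest
   expression → largest rank, average ranks on ties); the enrichment
   score of a set is the sum, down the ranked list, of the difference
   between the rank-weighted in-set ECDF (weight `rank^α`, α = 0.25)
   and the unweighted out-of-set ECDF. No range normalization by
   default, since scores are only compared within one dataset; a range
   option exists.

3. **Key pathways.** A pathway qualifies when its group activity score
   decreases monotonically normal → low → high (method 1), its
   per-group median ssGSEA score does the same, and the Kruskal–Wallis
   test across the three groups gives p < 0.05 (method 2). Candidates
   are ranked by the method-1 activity drop Δ = p(normal) − p(high) and
   the top k = 5 are retained. The magnitude criterion and k are
   parameters; the drop from normal to high-heterogeneity is the
   natural one-number summary of a monotone trend.

4. **Key cells.** Immune-cell infiltration is the ssGSEA score of each
   cell type's marker set. Within each of the three groups, samples
   with above-median mean key-pathway score form "high-activity"
   subgroups (the cutoff quantile is a parameter). A cell is selected
   when (a) its infiltration differs between every pair of subgroups
   (two-sided Wilcoxon rank-sum p < 0.05) and across all three
   (Kruskal–Wallis p < 0.05), and (b) its infiltration correlates with
   continuous MATH at Pearson R < −0.4 with Benjamini–Hochberg FDR
   < 0.01. The BH family is the full set of cell types tested;
   correlations use tumor samples only (normals carry no mutations).

5. **Subtypes.** Tumors are consensus-clustered on their key-cell
   infiltration profiles: 1,000 subsampling iterations at 80% of
   samples, base clusterer hierarchical agglomeration (average linkage)
   on `1 − Pearson` distance between profiles; a pair's consensus is
   its co-clustering frequency among co-sampled iterations. PAC (the
   fraction of off-diagonal consensus entries strictly inside
   (0.1, 0.9)) is the cluster-number diagnostic; the workflow default
   forces k = 2, the structure the analysis is designed to detect,
   with minimum-PAC selection available. Pairs never co-sampled are
   reported missing, never as zero — at the default depth every pair is
   expected to be co-sampled ~640 times, so a missing entry indicates a
   configuration error and aborts label extraction.

6. **Characterization.** Subtypes are compared by TMB (nonsynonymous
   mutations per 38 Mb exome, two-sided Wilcoxon), overall survival
   (Kaplan–Meier curves, log-rank test), per-metabolic-pathway
   univariate Cox fits within each subtype (features z-scored so the
   hazard ratio is per SD of pathway score; Efron ties; p < 0.05 flags
   RISK when HR > 1, PROTECTIVE when HR < 1), and metabolic-pathway ×
   key-cell Pearson correlation maps (unadjusted p < 0.05, BH optional).

## Preprocessing conventions

FPKM is rescaled per sample to TPM (`column / column-sum × 10⁶`).
Genes missing in strictly more than 50% of samples are dropped;
surviving missing entries are imputed to 0 — conservative, and keeps
the matrix dense — before the `log2(x + 1)` transform (the pseudocount
avoids −∞ at zero expression). Gene symbols are matched
case-sensitively; identifier mapping is the caller's responsibility.

## The synthetic cohort generator

The generator emulates a TCGA-style cohort — matched normals, tumor
expression, a MAF-like mutation table, GMT gene sets, survival — with
planted truth at every level, so each stage can be validated against a
known answer. Defaults: 50 normals, 150 tumors, 2,000 genes, 20 immune
pathways (15 genes each, 5 planted decreasing), 28 cell types (25
markers each, 9 planted), 10 metabolic pathways, 100–300 mutations per
tumor, log2 noise SD 0.8.

* **VAFs.** Low-heterogeneity tumors draw from Beta(20, 20) (a tight
  clonal band around 0.5, MATH ≈ 15); high-heterogeneity tumors from
  the mixture 0.5·Beta(20, 20) + 0.5·Beta(5, 45) (a subclonal shoulder,
  MATH ≈ 60). Read depths are drawn per variant and allele counts
  re-derived, so recorded VAFs carry realistic discretization.
* **Pathway gradients.** Genes of planted pathways are shifted by
  +2·g, +1·g, +0 (g = `gradient_effect`, default 1.0 log2 units) in
  normal, low-het and high-het samples.
* **Cell–MATH correlation.** Each planted cell adds to its markers a
  per-sample signal `t = ρ·z(MATH) + √(1−ρ²)·(a·b + √(1−a²)·ε)` on the
  standardized scale, where ρ = `cell_corr` (−0.6), z(MATH) is the
  tumor's standardized realized MATH, b = ±1 encodes the subtype block
  and a = `subtype_sep` (0.8). Because the block pattern lives in the
  orthogonal complement of the MATH component, corr(signal, MATH) = ρ
  exactly in expectation regardless of block strength. The observable
  ssGSEA-score correlation is mildly compressed by the rank transform
  (≈ −0.54 at ρ = −0.6).
* **Subtype blocks.** The two planted subtypes elevate complementary
  halves of the planted cell set (b = +1 for "their" cells). A shift
  common to all cells would be invisible to the `1 − Pearson` profile
  distance (correlation is shift-invariant), so the planted structure
  must be a pattern, not a level.
* **Normals.** Normal samples carry no mutation records and receive an
  elevated planted-cell level (2.2 standardized units), placing them
  above the low-heterogeneity tumors so the planted infiltration trend
  normal > low-het > high-het is real and strictly monotone.
* **Survival.** Event times are exponential with hazard `h₀` (subtype
  1) and `h₀·HR` (subtype 2, HR = 2 by default); censoring times are
  Uniform(0, b) independent of the event process, with b calibrated by
  root-finding so the expected censored fraction equals `censor_rate`
  (0.25). Independence keeps Cox and log-rank estimates unbiased — a
  censoring time constructed from the event time itself would be
  informative and was measurably biased when tried.
* **Determinism.** One seed feeds a `SeedSequence`; per-component
  sub-streams (assignment, mutations, expression, survival) keep draws
  stable when unrelated parameters change. Identical configurations
  produce byte-identical output files.

What the generator does **not** emulate: mutational signatures and
gene-level mutation hotspots, copy-number distortion of VAFs, batch and
purity effects, correlated marker genes within a cell type, and
microarray-style probe structure. Passing the recovery tests therefore
shows the statistical machinery is correct and calibrated under the
model's assumptions, not that the biological conclusions transfer to
any particular real dataset.

## Problem sizes in tests and the acceptance script

Recovery runs use the default cohort (150 tumors + 50 normals, 2,000
genes) — 20 seeds for selection recovery. Calibration runs use
deliberately smaller null cohorts (80 tumors + 20 normals, 1,200 genes,
zero planted effects; 100–200 replicates) and survival-only replicates
(250 per subtype, 50–100 replicates), sizes chosen to give stable Monte
Carlo summaries. Stochastic assertions fix their seeds; the null
uniformity check is a Kolmogorov–Smirnov test at the 1% level, so any
fixed seed family carries that nominal false-alarm risk (the shipped
family was verified against a larger independent batch).

## Numerical choices and degenerate inputs

* Ties: average ranks inside ssGSEA; ordering among exactly tied
  expression values is stable (input order). Median-tie tumors go to
  the LOW group. Trend comparisons use a tolerance `eps` (default 0 —
  exact ties are vanishingly likely on continuous scores) and ties
  yield an UNDETERMINED class excluded from selection.
* Undefined scores are flagged, not silently zeroed: gene sets covering
  no expressed gene (or all of them), constant infiltration vectors,
  non-converging Cox fits and under-mutated tumors all produce NaN/flag
  paths with warnings.
* MATH is scale-invariant (a ratio), and `median = 0` is impossible for
  VAFs in (0, 1] after filtering but guarded anyway.
* BH adjustment preserves input order and enforces step-up
  monotonicity; it is validated against a hand-rolled reference.
* Pearson distances are symmetrized and clipped to [−1, 1] before
  linkage to absorb floating-point asymmetry.

## Known limitations

* The three-group design assumes matched normal expression is
  available; without normals the trend classification degenerates to
  two points and is not supported.
* ssGSEA scores are compared within one dataset only; no cross-cohort
  normalization is provided.
* Univariate Cox per pathway ignores correlation between pathways;
  hazard ratios are marginal, not adjusted.
* The consensus base clusterer inside each iteration is a configuration
  choice (average/complete/ward); results at small sample sizes can be
  linkage-sensitive.
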