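# ithimmune

Linking intra-tumoral heterogeneity to the immune landscape of bulk
tumor cohorts.

Tumors are genetically heterogeneous, and heterogeneity shapes — and is
shaped by — the immune microenvironment. `ithimmune` is a tested,
reusable implementation of an integrative analysis for cohorts with
bulk expression, somatic mutations, matched normals and survival
follow-up. It is written for computational biologists who want each
stage available as a library function (or CLI subcommand) rather than a
one-off script, and it ships a synthetic-cohort generator with planted
ground truth so the whole chain is verifiable without any external
download.

## What it computes

1. **MATH score** per tumor: `MATH = 100 × MAD / median` of the
   somatic variant allele fractions (MAD scaled by 1.4826); tumors are
   split at the cohort median into low/high-heterogeneity groups,
   giving three ordered groups with the matched normals.
2. **Immune pathway activity** by two methods over the groups
   normal → low-het → high-het:
   - the group-level weighted relative-expression score
     `p_tj = Σᵢ wᵢ·r_ij / Σᵢ wᵢ`, with `r_ij = E_ij / mean_j E_ij` the
     relative group-mean expression of gene *i* and `wᵢ` the reciprocal
     of the gene's pathway multiplicity;
   - per-sample ssGSEA: the running-sum enrichment
     `ES = Σ_position [P_inʷ(i) − P_out(i)]` with rank weights
     `|rank|^α`, α = 0.25.
3. **Key pathways**: monotone-decreasing trend by both methods plus
   Kruskal–Wallis p < 0.05, ranked by the normal-to-high activity drop
   (top 5 by default).
4. **Key immune cells**: marker-set ssGSEA infiltration that (a)
   separates all pairs of high-key-pathway-activity subgroups (Wilcoxon
   p < 0.05; Kruskal–Wallis p < 0.05) and (b) correlates with MATH at
   Pearson R < −0.4 with BH-FDR < 0.01.
5. **Immune subtypes**: consensus clustering of tumors on key-cell
   infiltration (1,000 iterations, 80% subsampling, 1 − Pearson
   distance, PAC diagnostic; k = 2 by default).
6. **Subtype characterization**: TMB comparison (Wilcoxon),
   Kaplan–Meier / log-rank survival, univariate Cox on metabolic
   pathway scores (HR per SD, RISK/PROTECTIVE at p < 0.05), and
   metabolic-pathway × key-cell correlation maps.

See `docs/methods.md` for the model details, the synthetic generator's
design and the numerical conventions.

## Worked example

```python
import ithimmune as it

cfg = it.SimConfig(seed=11)           # synthetic cohort: 50 normals, 150 tumors
cohort = it.simulate_cohort(cfg)
normals = [s for s, g in cohort.truth.sample_group.items() if g == "NORMAL"]

res = it.run_pipeline(
    cohort.expression, cohort.mutations, cohort.pathways,
    cohort.cell_markers, normals,
    clinical=cohort.clinical, metabolic=cohort.metabolic, seed=11,
)
```

Printing the stage results of this exact run:

```text
median MATH threshold: 26.07
low / high het tumors: 75 / 75
key pathways: ['PATHWAY_02', 'PATHWAY_04', 'PATHWAY_03', 'PATHWAY_01', 'PATHWAY_05']
key cells: ['CELL_01', 'CELL_02', ..., 'CELL_09']
subtype sizes: {2: 75, 1: 75}  ARI vs planted truth: 1.0
log-rank p: 1.55e-03
TMB medians: {2: 4.24, 1: 4.63}  Wilcoxon p: 0.233
```

Reading the output: the cohort median MATH (26.07) splits the 150
tumors 75/75; the five pathways planted with a decreasing activity
gradient are exactly the five selected (order = ranked activity drop);
all nine cells planted with negative MATH correlation pass both
filters; consensus clustering recovers the planted two-block subtype
structure perfectly (adjusted Rand index 1.0), and the subtypes differ
in overall survival (log-rank p ≈ 0.002, planted hazard ratio 2). TMB
was not planted to differ between subtypes, and accordingly the
Wilcoxon test finds no difference.

The same stages are exposed as CLI subcommands
(`ithimmune generate | math | tmb | score-pathways | select-cells |
cluster | characterize`); run `ithimmune --help`.

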