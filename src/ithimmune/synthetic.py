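"""Synthetic cohort generator with planted ground truth.

Emulates the inputs of the heterogeneity/immune analysis — a bulk
expression matrix with matched normals, a MAF-like somatic mutation
table, immune-pathway / cell-marker / metabolic gene sets, and a
survival table — with known structure planted at every level:

* *heterogeneity*: half the tumors draw variant allele fractions from a
  concentrated clonal distribution (low MATH), half from a
  clonal + subclonal mixture (high MATH);
* *pathway gradients*: genes of the planted "decreasing" pathways are
  shifted in log2 expression by +2, +1, +0 gradient units in normal,
  low- and high-heterogeneity samples;
* *cell-heterogeneity correlation*: marker genes of the planted key
  cells carry a per-sample signal constructed to have a target Pearson
  correlation with the sample's realized MATH score;
* *subtypes*: two complementary halves of the planted cell set are
  elevated in two tumor blocks, giving anti-correlated infiltration
  profiles that consensus clustering can recover (a shift common to all
  cells would be invisible to a correlation distance);
* *survival*: exponential event times with a subtype hazard ratio and
  independent uniform censoring.

One seed determines everything; independent sub-streams per component
keep draws stable when unrelated parts of the configuration change.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import heterogeneity
from .heterogeneity import HIGH_HET, LOW_HET, NORMAL
from .io_formats import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    MutationTable,
    Units,
    write_clinical,
    write_expression,
    write_gmt,
    write_mutations,
)

logger = logging.getLogger("ithimmune")

LOW = "LOW"
HIGH = "HIGH"


@dataclass
class VafParams:
    """Beta parameters of the low/high heterogeneity VAF distributions.

    LOW draws from a single concentrated clonal component; HIGH draws
    from a mixture of the clonal component and a low-frequency
    subclonal component.
    """

    low: Tuple[float, float] = (20.0, 20.0)
    high_clonal: Tuple[float, float] = (20.0, 20.0)
    high_subclonal: Tuple[float, float] = (5.0, 45.0)
    high_subclonal_weight: float = 0.5


@dataclass
class SimConfig:
    """Cohort-level simulation parameters (units noted per field).

    Effect sizes are in log2-expression units; hazards are events per
    unit time of the survival table.
    """

    n_normal: int = 50
    n_tumor: int = 150
    n_genes: int = 2000
    n_pathways: int = 20
    n_planted_pathways: int = 5
    genes_per_pathway: int = 15
    n_cells: int = 28
    n_planted_cells: int = 9
    markers_per_cell: int = 25
    n_metabolic: int = 10
    genes_per_metabolic: int = 15
    gradient_effect: float = 1.0        # log2 shift per group step in planted pathways
    cell_corr: float = -0.6             # target Pearson r(planted-cell signal, MATH)
    cell_effect: float = 1.0            # log2 amplitude of the per-sample cell signal
    subtype_sep: float = 0.8            # fraction (0..1) of non-MATH cell variance aligned with the subtype blocks
    normal_cell_level: float = 2.2      # normals' cell signal on the standardized scale
    noise_sd: float = 0.8               # per-gene, per-sample log2 noise
    baseline_mean: float = 6.0          # mean baseline log2 expression
    baseline_sd: float = 1.5
    n_mut_range: Tuple[int, int] = (100, 300)
    vaf_params: VafParams = field(default_factory=VafParams)
    depth_range: Tuple[int, int] = (60, 200)
    n_dropout_genes: int = 5            # background genes with >50% missing entries
    missing_frac: float = 0.005         # scattered missingness in background genes
    baseline_hazard: float = 0.02
    hazard_ratio: float = 2.0
    censor_rate: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_normal", "n_tumor", "n_genes", "n_pathways", "n_cells",
                     "genes_per_pathway", "markers_per_cell"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if not -1 < self.cell_corr < 0:
            raise ValueError("cell_corr must lie in (-1, 0)")
        if not 0 <= self.subtype_sep < 1:
            raise ValueError("subtype_sep must lie in [0, 1)")


@dataclass
class CohortTruth:
    """Planted ground truth of one simulated cohort."""

    sample_group: Dict[str, str]              # sample -> NORMAL / LOW_HET / HIGH_HET
    target_math: Dict[str, float]             # tumor -> realized MATH score
    decreasing_pathways: Set[str]
    key_cells_true: Set[str]
    subtype_true: Dict[str, int]              # tumor -> 1 / 2
    hazard_ratio_true: float

    def __post_init__(self) -> None:
        if self.hazard_ratio_true <= 0:
            raise ValueError("hazard_ratio_true must be positive")


@dataclass
class Cohort:
    """All generated inputs plus the truth used to generate them."""

    expression: ExpressionMatrix
    mutations: MutationTable
    pathways: GeneSetCollection
    cell_markers: GeneSetCollection
    metabolic: GeneSetCollection
    clinical: ClinicalTable
    truth: CohortTruth
    config: SimConfig


# ---------------------------------------------------------------------------
# Component simulators
# ---------------------------------------------------------------------------


def simulate_vafs(
    n_mut: int,
    mode: str,
    params: Optional[VafParams] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Draw variant allele fractions for one tumor.

    LOW mode uses a single concentrated Beta; HIGH mode a clonal /
    subclonal Beta mixture, yielding a wider allele-fraction spread and
    hence a larger MATH score. Fewer than 3 variants is an error.
    """
    if n_mut < 3:
        raise ValueError("need at least 3 variants per tumor")
    params = params or VafParams()
    rng = rng if rng is not None else np.random.default_rng()
    if mode == LOW:
        a, b = params.low
        vafs = rng.beta(a, b, size=n_mut)
    elif mode == HIGH:
        sub = rng.random(n_mut) < params.high_subclonal_weight
        a1, b1 = params.high_clonal
        a2, b2 = params.high_subclonal
        vafs = np.where(sub, rng.beta(a2, b2, size=n_mut), rng.beta(a1, b1, size=n_mut))
    else:
        raise ValueError(f"unknown VAF mode {mode!r}")
    return np.clip(vafs, 1e-6, 1 - 1e-6)


def _gene_names(n: int) -> List[str]:
    return [f"GENE{i + 1:05d}" for i in range(n)]


def _layout_gene_sets(cfg: SimConfig, genes: Sequence[str]):
    """Allocate disjoint gene blocks to pathway / marker / metabolic sets."""
    need = (
        cfg.n_pathways * cfg.genes_per_pathway
        + cfg.n_cells * cfg.markers_per_cell
        + cfg.n_metabolic * cfg.genes_per_metabolic
    )
    if need > len(genes):
        raise ValueError(
            f"planted sets need {need} genes but n_genes = {len(genes)}"
        )
    pos = 0
    pathways: Dict[str, List[str]] = {}
    for t in range(cfg.n_pathways):
        pathways[f"PATHWAY_{t + 1:02d}"] = list(
            genes[pos:pos + cfg.genes_per_pathway]
        )
        pos += cfg.genes_per_pathway
    cells: Dict[str, List[str]] = {}
    for c in range(cfg.n_cells):
        cells[f"CELL_{c + 1:02d}"] = list(genes[pos:pos + cfg.markers_per_cell])
        pos += cfg.markers_per_cell
    metabolic: Dict[str, List[str]] = {}
    for m in range(cfg.n_metabolic):
        metabolic[f"METABOLIC_{m + 1:02d}"] = list(
            genes[pos:pos + cfg.genes_per_metabolic]
        )
        pos += cfg.genes_per_metabolic
    return pathways, cells, metabolic


def simulate_expression(
    cfg: SimConfig,
    truth: CohortTruth,
    rng: np.random.Generator,
) -> Tuple[ExpressionMatrix, GeneSetCollection, GeneSetCollection]:
    """Generate TPM-scale expression plus pathway and cell-marker sets.

    Requires ``truth`` to carry group assignments, realized MATH values
    and subtype labels. Signals are constructed in log2 space and
    exported as TPM = 2^log2 - 1, so downstream log2(TPM + 1)
    preprocessing recovers the constructed values exactly (up to the
    planted missing entries).
    """
    genes = _gene_names(cfg.n_genes)
    pathway_sets, cell_sets, _ = _layout_gene_sets(cfg, genes)
    samples = list(truth.sample_group)
    n_s = len(samples)
    gidx = {g: i for i, g in enumerate(genes)}

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    L = baseline[:, None] + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n_s))

    # planted pathway gradient: +2, +1, +0 gradient units across groups
    group_step = {NORMAL: 2.0, LOW_HET: 1.0, HIGH_HET: 0.0}
    shift = np.array([group_step[truth.sample_group[s]] for s in samples])
    planted_pw = sorted(truth.decreasing_pathways)
    for name in planted_pw:
        rows = [gidx[g] for g in pathway_sets[name]]
        L[np.ix_(rows, range(n_s))] += cfg.gradient_effect * shift[None, :]

    # planted cell signal: corr-controlled against realized MATH in tumors,
    # an elevated level in normals, plus the subtype block pattern
    tumors = [s for s in samples if truth.sample_group[s] != NORMAL]
    normals = [s for s in samples if truth.sample_group[s] == NORMAL]
    math_vals = np.array([truth.target_math[s] for s in tumors])
    z_math = (math_vals - math_vals.mean()) / math_vals.std()
    rho = cfg.cell_corr
    planted_cells = sorted(truth.key_cells_true)
    half = (len(planted_cells) + 1) // 2
    block_of = {c: (1 if i < half else 2) for i, c in enumerate(planted_cells)}
    s_pos = {s: j for j, s in enumerate(samples)}
    a = cfg.subtype_sep
    for cell in planted_cells:
        t = np.zeros(n_s)
        eps = rng.normal(size=len(tumors))
        # subtype block pattern lives inside the orthogonal complement of
        # the MATH component, so corr(signal, MATH) = cell_corr exactly in
        # expectation while block separation is controlled by subtype_sep
        b = np.array(
            [1.0 if truth.subtype_true[s] == block_of[cell] else -1.0
             for s in tumors]
        )
        resid = a * b + np.sqrt(1 - a ** 2) * eps
        t_tum = rho * z_math + np.sqrt(1 - rho ** 2) * resid
        for s, val in zip(tumors, t_tum):
            t[s_pos[s]] = val
        eps_n = rng.normal(size=len(normals))
        for s, e in zip(normals, eps_n):
            t[s_pos[s]] = cfg.normal_cell_level + 0.3 * e
        rows = [gidx[g] for g in cell_sets[cell]]
        L[rows, :] += cfg.cell_effect * t[None, :]

    tpm = np.maximum(np.exp2(L) - 1.0, 0.0)

    # planted missingness, confined to background genes
    set_genes = {g for gs in pathway_sets.values() for g in gs}
    set_genes |= {g for gs in cell_sets.values() for g in gs}
    background = [i for i, g in enumerate(genes) if g not in set_genes]
    if cfg.n_dropout_genes and background:
        drop_rows = rng.choice(background, size=min(cfg.n_dropout_genes,
                                                    len(background)), replace=False)
        for i in drop_rows:
            cols = rng.choice(n_s, size=max(int(0.8 * n_s), int(n_s // 2) + 1),
                              replace=False)
            tpm[i, cols] = np.nan
    if cfg.missing_frac > 0 and background:
        mask = rng.random((len(background), n_s)) < cfg.missing_frac
        bg = np.asarray(background)
        rr, cc = np.nonzero(mask)
        tpm[bg[rr], cc] = np.nan

    expr = ExpressionMatrix(
        values=pd.DataFrame(tpm, index=genes, columns=samples),
        unit_state=Units.TPM,
    )
    pw_coll = GeneSetCollection(
        sets=pathway_sets,
        descriptions={k: "immune pathway" for k in pathway_sets},
    )
    cell_coll = GeneSetCollection(
        sets=cell_sets,
        descriptions={k: "cell markers" for k in cell_sets},
    )
    return expr, pw_coll, cell_coll


def simulate_survival(
    truth: CohortTruth,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> ClinicalTable:
    """Exponential survival with a subtype hazard ratio and uniform censoring.

    Subtype 2 tumors have hazard ``baseline_hazard * hazard_ratio_true``.
    Censoring times are drawn Uniform(0, b) independently of the event
    process, with b calibrated so the expected censored fraction equals
    ``censor_rate``; a sample is censored when its censoring time falls
    before its event time. Independence keeps the Cox and log-rank
    estimates unbiased.
    """
    if truth.hazard_ratio_true <= 0:
        raise ValueError("hazard_ratio_true must be positive")
    samples = list(truth.subtype_true)
    n = len(samples)
    h = np.array(
        [
            cfg.baseline_hazard
            * (truth.hazard_ratio_true if truth.subtype_true[s] == 2 else 1.0)
            for s in samples
        ]
    )
    event_times = rng.exponential(1.0 / h)
    if cfg.censor_rate >= 1.0:
        obs = rng.uniform(0.0, 1.0 / h.mean(), size=n)
        events = np.zeros(n, dtype=int)
    elif cfg.censor_rate <= 0.0:
        obs = event_times
        events = np.ones(n, dtype=int)
    else:
        # P(censored | hazard h, bound b) = (1 - exp(-h b)) / (h b)
        from scipy.optimize import brentq

        def censored_frac(b):
            return float(np.mean((1.0 - np.exp(-h * b)) / (h * b)))

        b = brentq(lambda x: censored_frac(x) - cfg.censor_rate,
                   1e-9 / h.mean(), 1e6 / h.mean())
        censor_times = rng.uniform(0.0, b, size=n)
        events = (event_times <= censor_times).astype(int)
        obs = np.minimum(event_times, censor_times)
    rec = pd.DataFrame({"sample": samples, "time": obs, "event": events})
    return ClinicalTable(records=rec)


# ---------------------------------------------------------------------------
# Cohort orchestration
# ---------------------------------------------------------------------------

_VARIANT_CLASSES = ["Missense_Mutation", "Silent", "Nonsense_Mutation", "Splice_Site"]
_VARIANT_PROBS = [0.70, 0.18, 0.08, 0.04]


def simulate_cohort(cfg: SimConfig) -> Cohort:
    """Generate a complete cohort from one seed.

    Sub-streams are derived per component (assignment, mutations,
    expression, survival) from the single configuration seed.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_assign, rng_mut, rng_expr, rng_surv = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )

    normals = [f"NORM_{i + 1:03d}" for i in range(cfg.n_normal)]
    tumors = [f"TUM_{i + 1:03d}" for i in range(cfg.n_tumor)]
    n_low = cfg.n_tumor // 2
    mode_of = {s: (LOW if i < n_low else HIGH) for i, s in enumerate(tumors)}
    sample_group = {s: NORMAL for s in normals}
    sample_group.update(
        {s: (LOW_HET if mode_of[s] == LOW else HIGH_HET) for s in tumors}
    )
    perm = rng_assign.permutation(cfg.n_tumor)
    subtype_true = {
        tumors[i]: (1 if rank < cfg.n_tumor // 2 else 2)
        for rank, i in enumerate(perm)
    }

    # --- mutations -------------------------------------------------------
    gene_pool = _gene_names(cfg.n_genes)
    recs = []
    lo, hi = cfg.n_mut_range
    for s in tumors:
        n_mut = int(rng_mut.integers(lo, hi + 1))
        vafs = simulate_vafs(n_mut, mode_of[s], cfg.vaf_params, rng_mut)
        depth = rng_mut.integers(cfg.depth_range[0], cfg.depth_range[1] + 1,
                                 size=n_mut)
        alt = np.maximum(1, np.rint(vafs * depth).astype(int))
        alt = np.minimum(alt, depth)
        mut_genes = rng_mut.choice(gene_pool, size=n_mut, replace=True)
        classes = rng_mut.choice(_VARIANT_CLASSES, size=n_mut, p=_VARIANT_PROBS)
        for g, vc, a, d in zip(mut_genes, classes, alt, depth):
            recs.append((s, g, vc, int(a), int(d - a)))
    mutations = MutationTable(
        records=pd.DataFrame(
            recs, columns=["sample", "gene", "variant_class", "alt_count", "ref_count"]
        )
    )

    scores = heterogeneity.math_table(mutations)
    target_math = {
        s: float(scores.loc[s, "math"]) for s in tumors if bool(scores.loc[s, "scored"])
    }
    if len(target_math) < cfg.n_tumor:
        logger.warning("%d tumors have undefined MATH",
                       cfg.n_tumor - len(target_math))

    pathway_names = [f"PATHWAY_{t + 1:02d}" for t in range(cfg.n_pathways)]
    cell_names = [f"CELL_{c + 1:02d}" for c in range(cfg.n_cells)]
    truth = CohortTruth(
        sample_group=sample_group,
        target_math=target_math,
        decreasing_pathways=set(pathway_names[: cfg.n_planted_pathways]),
        key_cells_true=set(cell_names[: cfg.n_planted_cells]),
        subtype_true=subtype_true,
        hazard_ratio_true=cfg.hazard_ratio,
    )

    expr, pw_coll, cell_coll = simulate_expression(cfg, truth, rng_expr)
    _, _, metab_sets = _layout_gene_sets(cfg, _gene_names(cfg.n_genes))
    metab_coll = GeneSetCollection(
        sets=metab_sets, descriptions={k: "metabolic pathway" for k in metab_sets}
    )
    clinical = simulate_survival(truth, cfg, rng_surv)
    return Cohort(
        expression=expr,
        mutations=mutations,
        pathways=pw_coll,
        cell_markers=cell_coll,
        metabolic=metab_coll,
        clinical=clinical,
        truth=truth,
        config=cfg,
    )


def write_cohort(cohort: Cohort, outdir) -> Dict[str, Path]:
    """Write every cohort artifact (plus truth.json) into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "mutations": outdir / "mutations.maf.tsv",
        "pathways": outdir / "pathways.gmt",
        "cell_markers": outdir / "cell_markers.gmt",
        "metabolic": outdir / "metabolic.gmt",
        "clinical": outdir / "clinical.tsv",
        "truth": outdir / "truth.json",
    }
    write_expression(cohort.expression, paths["expression"])
    write_mutations(cohort.mutations, paths["mutations"])
    write_gmt(cohort.pathways, paths["pathways"])
    write_gmt(cohort.cell_markers, paths["cell_markers"])
    write_gmt(cohort.metabolic, paths["metabolic"])
    write_clinical(cohort.clinical, paths["clinical"])
    truth = cohort.truth
    payload = {
        "sample_group": truth.sample_group,
        "target_math": truth.target_math,
        "decreasing_pathways": sorted(truth.decreasing_pathways),
        "key_cells_true": sorted(truth.key_cells_true),
        "subtype_true": truth.subtype_true,
        "hazard_ratio_true": truth.hazard_ratio_true,
        "config": dataclasses.asdict(cohort.config),
    }
    with paths["truth"].open("w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return paths
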