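"""End-to-end orchestration of the heterogeneity/immune analysis.

Runs the full chain on in-memory inputs: expression preprocessing,
MATH scoring and median split, dual pathway scoring and key-pathway
selection, infiltration scoring and key-cell selection, consensus
subtyping on the key cells, and subtype characterization (TMB,
survival, metabolic Cox, pathway-cell correlations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import pandas as pd

from . import (
    cell_selection,
    heterogeneity,
    io_formats,
    outcome_stats,
    pathway_activity,
    subtyping,
)
from .heterogeneity import NORMAL
from .io_formats import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    MutationTable,
    Units,
)

logger = logging.getLogger("ithimmune")


@dataclass
class PipelineResult:
    """Everything the pipeline computes, stage by stage."""

    math_scores: pd.DataFrame
    het_groups: heterogeneity.HetGrouping
    groups: Dict[str, str]                      # incl. NORMAL for normals
    activity: pd.DataFrame                      # Locasale pathway x group
    pathway_ssgsea: pd.DataFrame                # pathway x sample
    key_pathways: pathway_activity.KeyPathwaySelection
    infiltration: pd.DataFrame                  # cell x sample
    in_subgroup: pd.Series
    cell_report: cell_selection.CellSelectionReport
    consensus: Optional[subtyping.ConsensusResult] = None
    subtype_labels: Optional[pd.Series] = None
    tmb: Optional[pd.DataFrame] = None
    tmb_comparison: Optional[tuple] = None
    survival: Optional[outcome_stats.SurvivalComparison] = None
    metabolic_ssgsea: Optional[pd.DataFrame] = None
    cox_by_subtype: Dict[object, pd.DataFrame] = field(default_factory=dict)
    correlation_by_subtype: Dict[object, pd.DataFrame] = field(default_factory=dict)


def run_pipeline(
    expression: ExpressionMatrix,
    mutations: MutationTable,
    pathways: GeneSetCollection,
    cell_markers: GeneSetCollection,
    normal_samples: Sequence[str],
    clinical: Optional[ClinicalTable] = None,
    metabolic: Optional[GeneSetCollection] = None,
    k: int = 5,
    n_subtypes: Optional[int] = 2,
    consensus_iters: int = subtyping.DEFAULT_N_ITER,
    consensus_frac: float = subtyping.DEFAULT_SUBSAMPLE_FRAC,
    seed: int = subtyping.DEFAULT_SEED,
    do_subtyping: bool = True,
) -> PipelineResult:
    """Run the analysis end to end.

    ``normal_samples`` identifies matched-normal expression columns;
    all other expression samples are treated as tumors. With
    ``n_subtypes=None`` the cluster number is chosen by minimum PAC
    over 2..6; otherwise it is forced (the analysis default is 2).
    """
    # --- preprocessing ---------------------------------------------------
    if expression.unit_state is Units.FPKM:
        expression = io_formats.fpkm_to_tpm(expression)
    if expression.unit_state is Units.TPM:
        expression = io_formats.preprocess_expression(expression)

    # --- heterogeneity ---------------------------------------------------
    scores = heterogeneity.math_table(mutations)
    het = heterogeneity.assign_het_groups(scores)
    groups: Dict[str, str] = {s: NORMAL for s in normal_samples}
    groups.update(het.groups.to_dict())

    # --- pathway activity, both methods ----------------------------------
    E = pathway_activity.group_mean_expression(expression, groups)
    r = pathway_activity.relative_expression(E)
    activity = pathway_activity.weighted_pathway_activity(r, pathways)
    pw_scores = pathway_activity.ssgsea(expression, pathways)
    key_pw = pathway_activity.select_key_pathways(activity, pw_scores, groups, k=k)

    # --- infiltration and key cells --------------------------------------
    infiltration = cell_selection.infiltration_scores(expression, cell_markers)
    in_subgroup = cell_selection.select_subgroups(
        pw_scores.loc[key_pw.selected], groups
    )
    math_series = scores.loc[scores["scored"].astype(bool), "math"]
    cell_report = cell_selection.key_cell_filters(
        infiltration, in_subgroup, groups, math_series
    )
    result = PipelineResult(
        math_scores=scores,
        het_groups=het,
        groups=groups,
        activity=activity,
        pathway_ssgsea=pw_scores,
        key_pathways=key_pw,
        infiltration=infiltration,
        in_subgroup=in_subgroup,
        cell_report=cell_report,
    )

    # --- subtyping on key cells ------------------------------------------
    if not do_subtyping:
        return result
    key_cells = cell_report.selected
    if len(key_cells) < 2:
        logger.warning("fewer than 2 key cells selected; subtyping skipped")
        return result
    tumors = [s for s in expression.sample_ids if s not in set(normal_samples)]
    k_range = (2, 3, 4, 5, 6) if n_subtypes is None else (n_subtypes,)
    if n_subtypes is None:
        k_range = tuple(kk for kk in k_range if kk * 3 <= len(tumors))
    consensus = subtyping.consensus_cluster(
        result.infiltration.loc[key_cells, tumors],
        k_range=k_range,
        n_iter=consensus_iters,
        frac=consensus_frac,
        seed=seed,
    )
    result.consensus = consensus
    labels = consensus.labels[consensus.best_k]
    result.subtype_labels = labels

    # --- characterization -------------------------------------------------
    result.tmb = heterogeneity.compute_tmb(mutations, all_samples=tumors)
    if labels.nunique() == 2:
        result.tmb_comparison = outcome_stats.tmb_compare(
            result.tmb, labels.to_dict()
        )
    if clinical is not None:
        have_clin = set(clinical.sample_ids)
        lab = labels[labels.index.isin(have_clin)]
        result.survival = outcome_stats.km_logrank(clinical, lab.to_dict())
        if metabolic is not None:
            metab_scores = pathway_activity.ssgsea(expression, metabolic)
            result.metabolic_ssgsea = metab_scores
            for subtype in sorted(lab.unique()):
                members = list(lab.index[lab == subtype])
                try:
                    result.cox_by_subtype[subtype] = outcome_stats.univariate_cox(
                        clinical, metab_scores[members]
                    )
                except ValueError as exc:
                    logger.warning("cox skipped for subtype %s: %s", subtype, exc)
                result.correlation_by_subtype[subtype] = (
                    outcome_stats.pathway_cell_correlation(
                        metab_scores, result.infiltration.loc[key_cells],
                        lab.to_dict(), subtype,
                    )
                )
    return result
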