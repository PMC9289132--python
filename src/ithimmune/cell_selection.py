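"""Immune-cell infiltration scoring and key-cell selection.

Infiltration of each immune-cell type is the ssGSEA score of its marker
gene set in each sample. Two independent filters define the key cells:

* *pathway filter* — within the high-key-pathway-activity subgroups
  (subnormal / sub-low / sub-high), the cell's infiltration differs
  between every pair of subgroups (two-sided Wilcoxon rank-sum p < 0.05)
  and across the three (Kruskal-Wallis p < 0.05);
* *heterogeneity filter* — the cell's infiltration correlates negatively
  with continuous MATH across tumor samples, Pearson R < -0.4 with
  Benjamini-Hochberg FDR < 0.01 over the full cell family.

A cell is selected iff it passes both filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, GeneSetCollection
from .pathway_activity import (
    DEFAULT_SSGSEA_ALPHA,
    GROUP_ORDER,
    ssgsea,
    test_group_differences,
)

logger = logging.getLogger("ithimmune")


def infiltration_scores(
    m: ExpressionMatrix,
    markers: GeneSetCollection,
    alpha: float = DEFAULT_SSGSEA_ALPHA,
) -> pd.DataFrame:
    """ssGSEA of each cell's marker set; markerless cells are dropped."""
    scores = ssgsea(m, markers, alpha=alpha)
    empty = scores.index[scores.isna().all(axis=1)]
    if len(empty):
        logger.warning("cells with no scorable markers excluded: %s", list(empty))
        scores = scores.drop(index=empty)
    return scores


def select_subgroups(
    key_scores: pd.DataFrame,
    groups: Mapping[str, str],
    cutoff_q: float = 0.5,
    group_order: Sequence[str] = GROUP_ORDER,
) -> pd.Series:
    """Mark, within each group, the samples with high key-pathway activity.

    The per-sample aggregate is the mean ssGSEA score over the key
    pathways; a sample enters its group's subgroup when its aggregate
    exceeds the within-group ``cutoff_q`` quantile. Groups smaller than
    4 make the quantile unstable and raise.
    """
    if not 0 <= cutoff_q <= 1:
        raise ValueError("cutoff_q must be in [0, 1]")
    aggregate = key_scores.mean(axis=0)
    in_subgroup = pd.Series(False, index=aggregate.index, name="in_subgroup")
    for g in group_order:
        members = [s for s in aggregate.index if groups.get(s) == g]
        if len(members) < 4:
            raise ValueError(f"group {g!r} has {len(members)} samples; need >= 4")
        vals = aggregate[members]
        cut = float(np.quantile(vals.to_numpy(), cutoff_q))
        in_subgroup[vals.index[vals > cut]] = True
    return in_subgroup


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class CellSelectionReport:
    """Per-cell statistics and the final key-cell list."""

    table: pd.DataFrame

    @property
    def selected(self):
        return list(self.table.index[self.table["selected"]])


def key_cell_filters(
    infiltration: pd.DataFrame,
    in_subgroup: pd.Series,
    groups: Mapping[str, str],
    math_scores: pd.Series,
    alpha_pairwise: float = 0.05,
    alpha_kw: float = 0.05,
    r_threshold: float = -0.4,
    fdr_threshold: float = 0.01,
    group_order: Sequence[str] = GROUP_ORDER,
) -> CellSelectionReport:
    """Apply the subgroup-difference and MATH-correlation filters.

    ``infiltration`` is cell x sample; ``math_scores`` maps tumor
    samples to continuous MATH. Correlations are computed on tumor
    samples only (normals carry no mutation data). Cells with constant
    infiltration are excluded with a warning (correlation undefined).
    """
    sub_samples = [s for s in infiltration.columns if in_subgroup.get(s, False)]
    sub_scores = infiltration[sub_samples]
    tests = test_group_differences(sub_scores, groups, group_order)
    pair_cols = [c for c in tests.columns if c.startswith("wilcoxon_p_")]

    tumor = [s for s in infiltration.columns if s in math_scores.index
             and np.isfinite(math_scores[s])]
    if len(tumor) < 3:
        raise ValueError("need >= 3 tumor samples with MATH for correlation")
    math_vec = math_scores[tumor].to_numpy(dtype=float)

    r_vals, p_vals = [], []
    for cell in infiltration.index:
        vec = infiltration.loc[cell, tumor].to_numpy(dtype=float)
        if np.all(vec == vec[0]) or np.all(math_vec == math_vec[0]):
            logger.warning("cell %s: constant vector; correlation undefined", cell)
            r_vals.append(np.nan)
            p_vals.append(np.nan)
            continue
        r, p = stats.pearsonr(vec, math_vec)
        r_vals.append(float(r))
        p_vals.append(float(p))
    r_arr = np.asarray(r_vals)
    p_arr = np.asarray(p_vals)
    # BH family = every cell tested; undefined correlations enter as p = 1
    fdr = bh_fdr(np.where(np.isfinite(p_arr), p_arr, 1.0))

    table = tests.copy()
    table["pearson_r"] = r_arr
    table["pearson_p"] = p_arr
    table["pearson_fdr"] = fdr
    table["passes_pathway_filter"] = (
        (table[pair_cols] < alpha_pairwise).all(axis=1)
        & (table["kw_p"] < alpha_kw)
    )
    table["passes_het_filter"] = (
        np.isfinite(r_arr) & (r_arr < r_threshold) & (fdr < fdr_threshold)
    )
    table["selected"] = table["passes_pathway_filter"] & table["passes_het_filter"]
    table.index.name = "cell"
    return CellSelectionReport(table=table)
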