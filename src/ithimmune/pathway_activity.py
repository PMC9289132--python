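"""Pathway activity scoring, trend classification and key-pathway selection.

Two complementary scorers are implemented:

**Group-level weighted relative-expression score** (Locasale method).
For gene *i* and group *j*, ``E_ij`` is the group-mean log2 expression;
``r_ij = E_ij / mean_j(E_ij)`` is the expression of the gene in group
*j* relative to its cross-group average; the activity of pathway *t* in
group *j* is the weighted average

    p_tj = sum_i(w_i * r_ij) / sum_i(w_i),   w_i = 1 / (# pathways containing gene i)

over the pathway's genes. The reciprocal-multiplicity weight discounts
genes shared across many pathways.

**Per-sample ssGSEA.** Genes are ranked within a sample (largest
expression -> largest rank, ties averaged); the enrichment score of a
set is the sum over the ranked list of the difference between the
rank-weighted in-set empirical CDF (weight ``|rank|^alpha``) and the
unweighted out-of-set empirical CDF.

Cross-group trends of either score are classified into four shapes
(monotone decreasing / increasing, down-then-up, up-then-down) over the
ordered groups normal -> low-heterogeneity -> high-heterogeneity, and
key pathways are those monotone-decreasing by both methods with a
significant Kruskal-Wallis difference, ranked by the normal-to-high
activity drop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .heterogeneity import HIGH_HET, LOW_HET, NORMAL
from .io_formats import ExpressionMatrix, GeneSetCollection, Units

logger = logging.getLogger("ithimmune")

#: Canonical group ordering: healthy tissue, then tumors of increasing
#: mutant-allele heterogeneity.
GROUP_ORDER: Tuple[str, str, str] = (NORMAL, LOW_HET, HIGH_HET)

DEFAULT_SSGSEA_ALPHA = 0.25


class TrendClass(str, Enum):
    DEC = "DEC"
    INC = "INC"
    DOWN_UP = "DOWN_UP"
    UP_DOWN = "UP_DOWN"
    UNDETERMINED = "UNDETERMINED"


# ---------------------------------------------------------------------------
# Method 1: group-level weighted relative expression
# ---------------------------------------------------------------------------


def group_mean_expression(
    m: ExpressionMatrix,
    groups: Mapping[str, str],
    group_order: Sequence[str] = GROUP_ORDER,
) -> pd.DataFrame:
    """Per-gene arithmetic mean of log2 expression within each group.

    ``groups`` maps each sample of interest to its group label; samples
    absent from the mapping are ignored. An empty group is an error.
    """
    if m.unit_state is not Units.LOG2TPM:
        raise ValueError("group means are computed on log2(TPM+1) expression")
    cols: Dict[str, np.ndarray] = {}
    for g in group_order:
        members = [s for s in m.sample_ids if groups.get(s) == g]
        if not members:
            raise ValueError(f"group {g!r} has no samples")
        cols[g] = m.values[members].mean(axis=1).to_numpy()
    return pd.DataFrame(cols, index=m.values.index)


def relative_expression(E: pd.DataFrame) -> pd.DataFrame:
    """r_ij = E_ij / mean over groups of E_ij; zero-mean genes dropped."""
    grand = E.mean(axis=1)
    zero = grand == 0
    if zero.any():
        logger.warning("relative_expression: dropped %d all-zero genes",
                       int(zero.sum()))
    Ez = E.loc[~zero]
    return Ez.div(grand[~zero], axis=0)


def pathway_weights(sets: GeneSetCollection) -> pd.Series:
    """w_i = 1 / number of sets in the collection containing gene i."""
    mult = sets.gene_multiplicity()
    return pd.Series({g: 1.0 / n for g, n in mult.items()}, name="weight")


def weighted_pathway_activity(
    r: pd.DataFrame,
    sets: GeneSetCollection,
    weights: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Weighted-average relative expression per (pathway, group).

    Genes listed in a set but absent from ``r`` are skipped (logged);
    a pathway with no genes present is excluded with a warning.
    """
    if weights is None:
        weights = pathway_weights(sets)
    rows: Dict[str, pd.Series] = {}
    for name in sets.names:
        genes = [g for g in sets[name] if g in r.index]
        n_missing = len(sets[name]) - len(genes)
        if n_missing:
            logger.info("pathway %s: %d genes absent from expression", name, n_missing)
        if not genes:
            logger.warning("pathway %s: no genes present; score undefined", name)
            continue
        w = weights.reindex(genes).to_numpy()
        sub = r.loc[genes].to_numpy()
        rows[name] = pd.Series((w @ sub) / w.sum(), index=r.columns)
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# Method 2: single-sample GSEA
# ---------------------------------------------------------------------------


def _ssgsea_sample(
    x: np.ndarray,
    membership: np.ndarray,
    alpha: float,
    normalize: bool,
) -> np.ndarray:
    """Enrichment scores of all sets for one sample.

    ``membership`` is a boolean (n_sets, n_genes) matrix aligned to the
    gene axis of ``x``.
    """
    n = x.size
    order = np.argsort(-x, kind="stable")
    # largest expression -> largest rank; ties share their average rank
    z = stats.rankdata(x)[order]
    w = np.abs(z) ** alpha
    memb = membership[:, order]
    m_sizes = memb.sum(axis=1)

    win = np.where(memb, w[None, :], 0.0)
    denom_in = win.sum(axis=1)
    out_sizes = n - m_sizes
    es = np.full(membership.shape[0], np.nan)
    valid = (m_sizes > 0) & (out_sizes > 0)
    if not valid.any():
        return es
    p_in = np.cumsum(win[valid], axis=1) / denom_in[valid, None]
    p_out = np.cumsum(~memb[valid], axis=1) / out_sizes[valid, None]
    running = p_in - p_out
    scores = running.sum(axis=1)
    if normalize:
        span = running.max(axis=1) - running.min(axis=1)
        scores = np.where(span > 0, scores / span, 0.0)
    es[valid] = scores
    return es


def ssgsea(
    m: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = DEFAULT_SSGSEA_ALPHA,
    normalize: bool = False,
) -> pd.DataFrame:
    """Single-sample enrichment score of every set in every sample.

    Scores are rank-based, hence invariant under strictly increasing
    transforms of a sample's expression. A set covering no expressed
    gene, or all of them, is undefined (NaN, logged).
    """
    if len(m.gene_ids) < 2:
        raise ValueError("ssGSEA needs at least 2 genes")
    gene_index = {g: i for i, g in enumerate(m.gene_ids)}
    n_genes = len(gene_index)
    membership = np.zeros((len(sets), n_genes), dtype=bool)
    for si, name in enumerate(sets.names):
        idx = [gene_index[g] for g in sets[name] if g in gene_index]
        membership[si, idx] = True
    sizes = membership.sum(axis=1)
    for si, name in enumerate(sets.names):
        if sizes[si] == 0:
            logger.warning("ssgsea: set %s has no genes in the matrix", name)
        elif sizes[si] == n_genes:
            logger.warning("ssgsea: set %s covers every gene; score undefined", name)

    X = m.values.to_numpy(dtype=float)
    out = np.empty((len(sets), X.shape[1]))
    for j in range(X.shape[1]):
        out[:, j] = _ssgsea_sample(X[:, j], membership, alpha, normalize)
    return pd.DataFrame(out, index=sets.names, columns=m.sample_ids)


# ---------------------------------------------------------------------------
# Trends, tests, selection
# ---------------------------------------------------------------------------


def classify_trend(
    s_normal: float, s_low: float, s_high: float, eps: float = 0.0
) -> TrendClass:
    """Shape of a score over the ordered groups normal -> low -> high.

    Differences with magnitude <= ``eps`` count as ties, yielding
    UNDETERMINED (excluded from selection).
    """
    d1 = s_normal - s_low
    d2 = s_low - s_high
    if abs(d1) <= eps or abs(d2) <= eps:
        return TrendClass.UNDETERMINED
    if d1 > 0 and d2 > 0:
        return TrendClass.DEC
    if d1 < 0 and d2 < 0:
        return TrendClass.INC
    if d1 > 0 and d2 < 0:
        return TrendClass.DOWN_UP
    return TrendClass.UP_DOWN


def test_group_differences(
    scores: pd.DataFrame,
    groups: Mapping[str, str],
    group_order: Sequence[str] = GROUP_ORDER,
) -> pd.DataFrame:
    """Kruskal-Wallis and pairwise Wilcoxon rank-sum tests per set.

    ``scores`` is set x sample. Returns one row per set with ``kw_p``
    and a two-sided Wilcoxon p-value per group pair. Sets constant
    across all groups get p = 1 with a warning.
    """
    members = {
        g: [s for s in scores.columns if groups.get(s) == g] for g in group_order
    }
    for g, mem in members.items():
        if len(mem) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 scored samples")
    pair_names = [
        (a, b) for i, a in enumerate(group_order) for b in group_order[i + 1:]
    ]
    rows = {}
    for name, row in scores.iterrows():
        vals = [row[mem].to_numpy(dtype=float) for mem in members.values()]
        if np.all(np.concatenate(vals) == np.concatenate(vals)[0]):
            logger.warning("set %s: constant scores; p-values set to 1", name)
            rows[name] = {"kw_p": 1.0, **{
                f"wilcoxon_p_{a.lower()}_{b.lower()}": 1.0 for a, b in pair_names
            }}
            continue
        kw_p = float(stats.kruskal(*vals).pvalue)
        entry = {"kw_p": kw_p}
        for (a, b) in pair_names:
            va = row[members[a]].to_numpy(dtype=float)
            vb = row[members[b]].to_numpy(dtype=float)
            if np.all(np.concatenate([va, vb]) == va[0]):
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue)
            entry[f"wilcoxon_p_{a.lower()}_{b.lower()}"] = p
        rows[name] = entry
    out = pd.DataFrame.from_dict(rows, orient="index").reindex(scores.index)
    out.index.name = "set"
    return out


@dataclass
class KeyPathwaySelection:
    """Per-pathway report plus the ranked key-pathway list."""

    report: pd.DataFrame
    selected: List[str]


def select_key_pathways(
    activity: pd.DataFrame,
    ssgsea_scores: pd.DataFrame,
    groups: Mapping[str, str],
    k: int = 5,
    alpha: float = 0.05,
    eps: float = 0.0,
    group_order: Sequence[str] = GROUP_ORDER,
) -> KeyPathwaySelection:
    """Intersect the two scorers' evidence and rank by activity drop.

    Candidates must show a monotone-decreasing group activity score
    (method 1), a monotone-decreasing per-group median ssGSEA score and
    a Kruskal-Wallis p < ``alpha`` (method 2). They are ranked by
    ``delta = p_(t,normal) - p_(t,high)``, the method-1 activity drop
    from normal to high-heterogeneity, and the top ``k`` are returned.
    """
    common = activity.index.intersection(ssgsea_scores.index)
    if len(common) == 0:
        raise ValueError("the two scorers share no pathways")
    tests = test_group_differences(ssgsea_scores.loc[common], groups, group_order)
    g_n, g_l, g_h = group_order
    medians = {
        g: ssgsea_scores.loc[
            common, [s for s in ssgsea_scores.columns if groups.get(s) == g]
        ].median(axis=1)
        for g in group_order
    }
    rows = {}
    for name in common:
        act = activity.loc[name]
        trend1 = classify_trend(act[g_n], act[g_l], act[g_h], eps)
        trend2 = classify_trend(
            medians[g_n][name], medians[g_l][name], medians[g_h][name], eps
        )
        kw_p = tests.loc[name, "kw_p"]
        rows[name] = {
            "trend_activity": trend1.value,
            "trend_ssgsea": trend2.value,
            "kw_p": kw_p,
            "delta": act[g_n] - act[g_h],
            "candidate": (
                trend1 is TrendClass.DEC
                and trend2 is TrendClass.DEC
                and kw_p < alpha
            ),
        }
    report = pd.DataFrame.from_dict(rows, orient="index")
    report = report.join(tests.drop(columns="kw_p"))
    report.index.name = "pathway"
    candidates = report[report["candidate"]].sort_values("delta", ascending=False)
    if len(candidates) < k:
        logger.warning("only %d candidate pathways for k=%d", len(candidates), k)
    selected = list(candidates.index[:k])
    report["selected"] = report.index.isin(selected)
    return KeyPathwaySelection(report=report, selected=selected)
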