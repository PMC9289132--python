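"""Characterization of immune subtypes: survival, TMB and metabolism.

Wraps standard survival machinery (Kaplan-Meier product-limit curves,
the log-rank test, univariate Cox proportional-hazards fits via
lifelines) and simple association statistics around subtype labels:

* overall-survival comparison between subtypes;
* tumor-mutational-burden comparison (two-sided Wilcoxon rank-sum);
* per-metabolic-pathway univariate Cox within a subtype, hazard ratios
  reported per standard deviation of the (z-scored) pathway score and
  classified RISK (HR > 1) / PROTECTIVE (HR < 1) at Wald p < 0.05;
* metabolic-pathway x immune-cell Pearson correlation maps within a
  subtype, flagged at unadjusted p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .cell_selection import bh_fdr
from .io_formats import ClinicalTable

logger = logging.getLogger("ithimmune")


@dataclass
class SurvivalComparison:
    """Per-group Kaplan-Meier curves plus the log-rank comparison."""

    curves: Dict[str, pd.DataFrame]  # group -> (time, survival, at_risk)
    logrank_chi2: float
    logrank_p: float


def _aligned_clinical(clin: ClinicalTable, labels: Mapping[str, object]) -> pd.DataFrame:
    rec = clin.records.set_index("sample")
    missing = [s for s in labels if s not in rec.index]
    if missing:
        raise ValueError(f"labeled samples without clinical records: {missing}")
    df = rec.loc[list(labels)].copy()
    df["label"] = [labels[s] for s in df.index]
    return df


def km_logrank(clin: ClinicalTable, labels: Mapping[str, object]) -> SurvivalComparison:
    """Kaplan-Meier estimate per labeled group and the log-rank test.

    Requires every labeled group to be non-empty and at least one event
    overall; the test is two-sided across all groups.
    """
    df = _aligned_clinical(clin, labels)
    if df["event"].sum() == 0:
        raise ValueError("no events observed; survival comparison undefined")
    groups = df["label"].unique()
    if any((df["label"] == g).sum() == 0 for g in groups):
        raise ValueError("empty group in survival comparison")
    curves = {}
    for g in groups:
        sub = df[df["label"] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        tbl = kmf.event_table
        curves[g] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index,
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
                "at_risk": tbl["at_risk"].reindex(
                    kmf.survival_function_.index
                ).to_numpy(),
            }
        ).reset_index(drop=True)
    res = multivariate_logrank_test(df["time"], df["label"], df["event"])
    return SurvivalComparison(
        curves=curves,
        logrank_chi2=float(res.test_statistic),
        logrank_p=float(res.p_value),
    )


def tmb_compare(
    tmb: pd.DataFrame, labels: Mapping[str, object]
) -> Tuple[Dict[object, float], float, str]:
    """Wilcoxon rank-sum comparison of TMB between two subtypes.

    Returns per-group medians, the two-sided p-value and a direction
    flag naming the higher-median group (``"none"`` on an exact tie).
    """
    vals = tmb["tmb"]
    by_group: Dict[object, np.ndarray] = {}
    for s, g in labels.items():
        if s in vals.index:
            by_group.setdefault(g, []).append(float(vals[s]))
    if len(by_group) != 2:
        raise ValueError(f"expected 2 subtypes, got {len(by_group)}")
    (ga, va), (gb, vb) = [(g, np.asarray(v)) for g, v in by_group.items()]
    if min(va.size, vb.size) < 2:
        raise ValueError("need >= 2 samples per subtype")
    pooled = np.concatenate([va, vb])
    if np.all(pooled == pooled[0]):
        logger.warning("all TMB values tied; p set to 1")
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(va, vb, alternative="two-sided").pvalue)
    medians = {ga: float(np.median(va)), gb: float(np.median(vb))}
    if medians[ga] > medians[gb]:
        direction = str(ga)
    elif medians[gb] > medians[ga]:
        direction = str(gb)
    else:
        direction = "none"
    return medians, p, direction


RISK = "RISK"
PROTECTIVE = "PROTECTIVE"


def univariate_cox(
    clin: ClinicalTable,
    feature_scores: pd.DataFrame,
    subtype_samples: Optional[Sequence[str]] = None,
    standardize: bool = True,
    alpha: float = 0.05,
    min_events: int = 10,
) -> pd.DataFrame:
    """One univariate Cox proportional-hazards fit per feature.

    ``feature_scores`` is feature x sample. With ``standardize`` each
    feature is z-scored before fitting so the hazard ratio is per
    standard deviation of score; otherwise raw units are used (e.g. a
    binary group indicator). Fits use the Efron tie approximation.
    Non-converging or degenerate features are reported as NaN rows
    rather than failing the batch.

    Returns a DataFrame per feature: log_hr, hr, ci95_low, ci95_high,
    wald_p, significant, risk_class.
    """
    rec = clin.records.set_index("sample")
    samples = [s for s in feature_scores.columns if s in rec.index]
    if subtype_samples is not None:
        wanted = set(subtype_samples)
        samples = [s for s in samples if s in wanted]
    if not samples:
        raise ValueError("no overlapping samples between scores and clinical")
    surv = rec.loc[samples, ["time", "event"]].astype(float)
    n_events = int(surv["event"].sum())
    if n_events < min_events:
        raise ValueError(f"{n_events} events in stratum, need >= {min_events}")

    rows = {}
    for feat in feature_scores.index:
        x = feature_scores.loc[feat, samples].to_numpy(dtype=float)
        na_row = dict(log_hr=np.nan, hr=np.nan, ci95_low=np.nan,
                      ci95_high=np.nan, wald_p=np.nan, significant=False,
                      risk_class="NA")
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            logger.warning("cox: feature %s constant; reported NA", feat)
            rows[feat] = na_row
            continue
        cov = (x - x.mean()) / sd if standardize else x
        df = surv.assign(score=cov)
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except Exception as exc:  # convergence failure -> NA, not a crash
            logger.warning("cox: feature %s failed to converge (%s)", feat, exc)
            rows[feat] = na_row
            continue
        log_hr = float(cph.params_["score"])
        se = float(cph.standard_errors_["score"])
        p = float(cph.summary.loc["score", "p"])
        rows[feat] = dict(
            log_hr=log_hr,
            hr=float(np.exp(log_hr)),
            ci95_low=float(np.exp(log_hr - 1.959963984540054 * se)),
            ci95_high=float(np.exp(log_hr + 1.959963984540054 * se)),
            wald_p=p,
            significant=p < alpha,
            risk_class=RISK if log_hr > 0 else PROTECTIVE,
        )
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "feature"
    return out


def pathway_cell_correlation(
    metab_scores: pd.DataFrame,
    infiltration: pd.DataFrame,
    labels: Mapping[str, object],
    subtype: object,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of each (metabolic pathway, immune cell) pair.

    Computed over the samples of one subtype; returns a long-format
    DataFrame (pathway, cell, pearson_r, p, significant). Pairs with a
    constant vector get NaN. With ``fdr`` the significance flag uses
    Benjamini-Hochberg adjusted p-values across all pairs.
    """
    samples = [
        s for s, g in labels.items()
        if g == subtype and s in metab_scores.columns and s in infiltration.columns
    ]
    if len(samples) < 3:
        raise ValueError(f"subtype {subtype!r} has {len(samples)} samples; need >= 3")
    rows = []
    for pw in metab_scores.index:
        x = metab_scores.loc[pw, samples].to_numpy(dtype=float)
        for cell in infiltration.index:
            y = infiltration.loc[cell, samples].to_numpy(dtype=float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                rows.append((pw, cell, np.nan, np.nan))
                continue
            r, p = stats.pearsonr(x, y)
            rows.append((pw, cell, float(r), float(p)))
    out = pd.DataFrame(rows, columns=["pathway", "cell", "pearson_r", "p"])
    if fdr:
        mask = out["p"].notna()
        adj = np.full(len(out), np.nan)
        adj[mask.to_numpy()] = bh_fdr(out.loc[mask, "p"].to_numpy())
        out["p_adj"] = adj
        out["significant"] = out["p_adj"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    return out
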