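"""Intra-tumoral heterogeneity (MATH) and tumor mutational burden.

The MATH score quantifies mutant-allele tumor heterogeneity as
``100 * MAD / median`` of a tumor's variant allele fractions (VAFs),
where MAD is the scaled median absolute deviation (constant 1.4826, the
consistency factor for a normal distribution). Higher MATH means a wider
spread of allele fractions, i.e. more subclonal structure.

Tumors are split into low- and high-heterogeneity groups at the cohort
median MATH; TMB is the count of nonsynonymous variants per megabase of
interrogated exome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .io_formats import MutationTable

logger = logging.getLogger("ithimmune")

#: VAF window retained for MATH; excludes likely germline / copy-number
#: affected variants (low and high extremes).
DEFAULT_VAF_RANGE: Tuple[float, float] = (0.075, 0.75)
DEFAULT_MIN_VARIANTS = 5
MAD_CONSTANT = 1.4826

#: Variant classes counted as nonsynonymous for TMB.
NONSYNONYMOUS_CLASSES: Set[str] = {
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Splice_Site",
    "Frame_Shift_Ins",
    "Frame_Shift_Del",
    "In_Frame_Ins",
    "In_Frame_Del",
    "Translation_Start_Site",
    "Nonstop_Mutation",
}

#: Recognized MAF variant classes (superset of the nonsynonymous ones).
KNOWN_CLASSES: Set[str] = NONSYNONYMOUS_CLASSES | {
    "Silent",
    "3'UTR",
    "5'UTR",
    "Intron",
    "RNA",
    "IGR",
    "3'Flank",
    "5'Flank",
}

LOW_HET = "LOW_HET"
HIGH_HET = "HIGH_HET"
NORMAL = "NORMAL"


class MathUndefinedError(ValueError):
    """MATH is undefined for the given variant set."""


def math_score(
    vafs: Sequence[float],
    min_variants: int = DEFAULT_MIN_VARIANTS,
    mad_constant: float = MAD_CONSTANT,
    vaf_range: Optional[Tuple[float, float]] = DEFAULT_VAF_RANGE,
) -> Tuple[float, float, float]:
    """Compute (median VAF, scaled MAD, MATH) for one tumor.

    Parameters
    ----------
    vafs
        Variant allele fractions in (0, 1].
    min_variants
        Minimum number of variants surviving the range filter; fewer
        raises :class:`MathUndefinedError`.
    mad_constant
        Scale factor applied to the raw median absolute deviation.
    vaf_range
        Inclusive (low, high) window of VAFs retained before scoring;
        ``None`` disables the filter.

    Returns
    -------
    (median, mad, math) where ``math = 100 * mad / median``.
    """
    arr = np.asarray(vafs, dtype=float)
    if arr.size and (np.nanmin(arr) <= 0 or np.nanmax(arr) > 1):
        raise ValueError("VAFs must lie in (0, 1]")
    arr = arr[~np.isnan(arr)]
    if vaf_range is not None:
        lo, hi = vaf_range
        arr = arr[(arr >= lo) & (arr <= hi)]
    if arr.size < min_variants:
        raise MathUndefinedError(
            f"{arr.size} variants after filtering, need >= {min_variants}"
        )
    med = float(np.median(arr))
    if med == 0:
        raise MathUndefinedError("median VAF is zero")
    mad = float(mad_constant * np.median(np.abs(arr - med)))
    return med, mad, 100.0 * mad / med


def math_table(
    muts: MutationTable,
    min_variants: int = DEFAULT_MIN_VARIANTS,
    mad_constant: float = MAD_CONSTANT,
    vaf_range: Optional[Tuple[float, float]] = DEFAULT_VAF_RANGE,
) -> pd.DataFrame:
    """Score every mutated sample; under-powered samples are flagged.

    Returns a DataFrame indexed by sample with columns ``n_variants_used``,
    ``median_vaf``, ``mad_vaf``, ``math`` and boolean ``scored``. Samples
    with too few variants keep NaN statistics and ``scored = False``
    rather than failing the whole cohort.
    """
    rows = {}
    for sample in muts.sample_ids:
        vafs = muts.vafs_for(sample)
        try:
            med, mad, math = math_score(vafs, min_variants, mad_constant, vaf_range)
            if vaf_range is not None:
                lo, hi = vaf_range
                n_used = int(((vafs >= lo) & (vafs <= hi)).sum())
            else:
                n_used = int(vafs.size)
            rows[sample] = dict(
                n_variants_used=n_used, median_vaf=med, mad_vaf=mad,
                math=math, scored=True,
            )
        except MathUndefinedError as exc:
            logger.warning("MATH undefined for %s: %s", sample, exc)
            rows[sample] = dict(
                n_variants_used=int(vafs.size), median_vaf=np.nan,
                mad_vaf=np.nan, math=np.nan, scored=False,
            )
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample"
    return out


@dataclass
class HetGrouping:
    """Low/high heterogeneity assignment with the median threshold used."""

    groups: pd.Series  # sample -> LOW_HET / HIGH_HET
    threshold: float

    def samples_in(self, group: str):
        return list(self.groups.index[self.groups == group])


def assign_het_groups(scores: pd.DataFrame) -> HetGrouping:
    """Median split of scored samples into LOW_HET (<= median) / HIGH_HET.

    Ties at the median are assigned LOW_HET, making the split
    deterministic. All scores identical is an error (no split exists).
    """
    scored = scores.loc[scores["scored"].astype(bool), "math"].dropna()
    if len(scored) < 2:
        raise ValueError("need at least 2 scored samples to split")
    if scored.nunique() == 1:
        raise ValueError("all MATH scores identical; no median split possible")
    threshold = float(scored.median())
    groups = pd.Series(
        np.where(scored.to_numpy() <= threshold, LOW_HET, HIGH_HET),
        index=scored.index, name="group",
    )
    return HetGrouping(groups=groups, threshold=threshold)


def compute_tmb(
    muts: MutationTable,
    exome_mb: float = 38.0,
    nonsyn_classes: Iterable[str] = frozenset(NONSYNONYMOUS_CLASSES),
    all_samples: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Nonsynonymous mutation count per megabase, per sample.

    Records with unrecognized variant classes are excluded with a
    warning. ``all_samples`` forces rows (tmb = 0, flagged
    ``no_mutations``) for samples absent from the mutation table.
    """
    nonsyn = set(nonsyn_classes)
    rec = muts.records
    unknown = set(rec["variant_class"]) - KNOWN_CLASSES - nonsyn
    if unknown:
        logger.warning("unknown variant classes excluded from TMB: %s",
                       sorted(unknown))
    counted = rec[rec["variant_class"].isin(nonsyn)]
    counts = counted.groupby("sample").size()
    samples = list(all_samples) if all_samples is not None else muts.sample_ids
    n_nonsyn = counts.reindex(samples, fill_value=0).astype(int)
    out = pd.DataFrame(
        {
            "n_nonsyn": n_nonsyn,
            "tmb": n_nonsyn / float(exome_mb),
            "no_mutations": ~pd.Index(samples).isin(rec["sample"]),
        }
    )
    out.index.name = "sample"
    return out
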