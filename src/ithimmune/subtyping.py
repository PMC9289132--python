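"""Consensus clustering of tumors on key-cell infiltration profiles.

Repeatedly subsamples the cohort (without replacement), clusters each
subsample by hierarchical agglomeration on the distance
``1 - Pearson correlation`` between samples' infiltration profiles, and
records for every sample pair how often it clusters together relative
to how often it was co-sampled. The consensus matrix entry for a pair
is that ratio; final subtype labels come from hierarchical clustering
of ``1 - consensus``.

The PAC statistic (proportion of ambiguously clustered pairs: consensus
entries strictly between two cutoffs) serves as the cluster-number
diagnostic — smaller is cleaner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger("ithimmune")

DEFAULT_K_RANGE: Tuple[int, ...] = (2, 3, 4, 5, 6)
DEFAULT_N_ITER = 1000
DEFAULT_SUBSAMPLE_FRAC = 0.8
DEFAULT_SEED = 1000


def _pearson_distance(X: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows, symmetrized, zero diagonal."""
    r = np.corrcoef(X)
    r = np.clip(r, -1.0, 1.0)
    d = 1.0 - r
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


@dataclass
class ConsensusResult:
    """Consensus matrices, labels and PAC diagnostics per cluster number."""

    consensus: Dict[int, pd.DataFrame]
    labels: Dict[int, pd.Series]
    pac: Dict[int, float]
    best_k: int
    params: Dict[str, object] = field(default_factory=dict)


def pac_statistic(
    consensus_matrix: pd.DataFrame | np.ndarray,
    lower: float = 0.1,
    upper: float = 0.9,
) -> float:
    """Fraction of off-diagonal consensus entries strictly inside (lower, upper)."""
    if lower >= upper:
        raise ValueError("lower bound must be below upper bound")
    arr = np.asarray(consensus_matrix, dtype=float)
    mask = ~np.eye(arr.shape[0], dtype=bool)
    vals = arr[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite off-diagonal consensus entries")
    return float(((vals > lower) & (vals < upper)).mean())


def consensus_cluster(
    profile: pd.DataFrame,
    k_range: Sequence[int] = DEFAULT_K_RANGE,
    n_iter: int = DEFAULT_N_ITER,
    frac: float = DEFAULT_SUBSAMPLE_FRAC,
    linkage_method: str = "average",
    seed: Optional[int] = DEFAULT_SEED,
) -> ConsensusResult:
    """Consensus clustering of the samples of a feature-by-sample profile.

    Parameters
    ----------
    profile
        Feature (key cell) x sample score matrix; samples are clustered
        on the correlation structure of their columns.
    k_range
        Cluster numbers to evaluate; the reported ``best_k`` minimizes
        PAC (a fixed k can be forced by passing a singleton range).
    n_iter, frac
        Number of subsampling iterations and the fraction of samples
        drawn (without replacement) per iteration.
    linkage_method
        Agglomeration rule for the base clusterer and the final cut
        (``average`` / ``complete`` / ``ward``).
    seed
        Seed of the subsampling stream; identical inputs and seed give
        identical consensus matrices.
    """
    if profile.shape[0] < 2:
        raise ValueError("need at least 2 features to correlate samples")
    samples = list(profile.columns)
    n = len(samples)
    k_range = tuple(int(k) for k in k_range)
    if n < max(k_range) * 3:
        raise ValueError(f"{n} samples too few for k up to {max(k_range)}")
    X = profile.to_numpy(dtype=float).T  # samples x features
    flat = X.std(axis=1) == 0
    if flat.any():
        bad = [samples[i] for i in np.flatnonzero(flat)]
        raise ValueError(f"zero-variance sample profile(s): {bad}")
    m = int(np.floor(frac * n))
    if max(k_range) >= m:
        raise ValueError(f"k={max(k_range)} >= subsample size {m}")

    rng = np.random.default_rng(seed)
    co_cluster = {k: np.zeros((n, n)) for k in k_range}
    co_sample = np.zeros((n, n))
    for _ in range(n_iter):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        block = np.ix_(idx, idx)
        co_sample[block] += 1.0
        D = _pearson_distance(X[idx])
        Z = linkage(squareform(D, checks=False), method=linkage_method)
        cuts = cut_tree(Z, n_clusters=list(k_range))
        for ki, k in enumerate(k_range):
            lab = cuts[:, ki]
            co_cluster[k][block] += (lab[:, None] == lab[None, :])

    never = co_sample == 0
    n_never = int(never.sum() - np.trace(never))
    if n_never:
        logger.warning("%d sample pairs never co-sampled; consensus missing", n_never)
    consensus: Dict[int, pd.DataFrame] = {}
    labels: Dict[int, pd.Series] = {}
    pac: Dict[int, float] = {}
    for k in k_range:
        with np.errstate(invalid="ignore", divide="ignore"):
            cm = co_cluster[k] / co_sample
        cm[never] = np.nan
        np.fill_diagonal(cm, 1.0)
        consensus[k] = pd.DataFrame(cm, index=samples, columns=samples)
        pac[k] = pac_statistic(cm)
        if np.isnan(cm[~np.eye(n, dtype=bool)]).any():
            raise ValueError(
                "missing consensus entries; increase n_iter or frac"
            )
        Zf = linkage(squareform(1.0 - cm, checks=False), method=linkage_method)
        lab = fcluster(Zf, t=k, criterion="maxclust")
        labels[k] = pd.Series(lab, index=samples, name="subtype")
    best_k = min(k_range, key=lambda k: pac[k])
    return ConsensusResult(
        consensus=consensus,
        labels=labels,
        pac=pac,
        best_k=best_k,
        params=dict(
            n_iter=n_iter, frac=frac, distance="pearson",
            linkage=linkage_method, seed=seed, k_range=k_range,
        ),
    )
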