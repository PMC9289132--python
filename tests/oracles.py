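"""Independent reference implementations used only by the tests.

Deliberately naive (pure Python, explicit loops) so they share no code
path with the package implementations they check.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence, Set


def _median(xs: Sequence[float]) -> float:
    s = sorted(xs)
    n = len(s)
    mid = n // 2
    if n % 2 == 1:
        return s[mid]
    return (s[mid - 1] + s[mid]) / 2.0


def math_oracle(vafs: Sequence[float], mad_constant: float = 1.4826):
    """Median / scaled-MAD / MATH by explicit sorting, no numpy."""
    med = _median(vafs)
    mad = mad_constant * _median([abs(v - med) for v in vafs])
    return med, mad, 100.0 * mad / med


def _average_ranks(values: Sequence[float]) -> List[float]:
    """Ranks 1..n, ties share their average rank."""
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def ssgsea_oracle(
    values: Sequence[float],
    genes: Sequence[str],
    gene_set: Iterable[str],
    alpha: float,
) -> float:
    """Running-sum enrichment score, position by position.

    Genes are walked in order of decreasing expression (stable among
    ties); at each position the weighted in-set ECDF (weight
    ``rank^alpha``) minus the unweighted out-of-set ECDF is accumulated.
    """
    gene_set = set(gene_set)
    n = len(values)
    ranks = _average_ranks(values)
    order = sorted(range(n), key=lambda i: (-values[i], i))
    in_set = [genes[i] in gene_set for i in order]
    weights = [abs(ranks[i]) ** alpha for i in order]
    sum_w_in = sum(w for w, m in zip(weights, in_set) if m)
    n_out = sum(1 for m in in_set if not m)
    if sum_w_in == 0 or n_out == 0:
        raise ValueError("degenerate gene set")
    es = 0.0
    cum_in = 0.0
    cum_out = 0.0
    for w, m in zip(weights, in_set):
        if m:
            cum_in += w / sum_w_in
        else:
            cum_out += 1.0 / n_out
        es += cum_in - cum_out
    return es


def bh_oracle(pvalues: Sequence[float]) -> List[float]:
    """Step-up Benjamini-Hochberg by the textbook definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        q = pvalues[i] * m / (pos + 1)
        running_min = min(running_min, q)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


def km_oracle(times: Sequence[float], events: Sequence[int]):
    """Product-limit estimate: list of (time, survival) at event times."""
    pairs = sorted(zip(times, events))
    n_at_risk = len(pairs)
    surv = 1.0
    out = []
    i = 0
    while i < len(pairs):
        t = pairs[i][0]
        d = sum(1 for tt, ee in pairs if tt == t and ee == 1)
        n = sum(1 for tt, _ in pairs if tt >= t)
        if d:
            surv *= 1.0 - d / n
            out.append((t, surv))
        while i < len(pairs) and pairs[i][0] == t:
            i += 1
    return out
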