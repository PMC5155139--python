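"""Templeton (winning-sites / Wilcoxon signed-rank) topology comparison.

Two trees are compared character by character: d_i = steps on tree A
minus steps on tree B.  Zero differences are dropped; the remaining
differences are ranked by absolute value (average ranks for ties) and a
two-sided Wilcoxon signed-rank test is applied.  With 25 or fewer
nonzero differences the null distribution of the rank sum is enumerated
exactly (a convolution over sign assignments, valid with tied ranks);
beyond that a normal approximation with continuity and tie corrections
is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .matrix import CharacterMatrix
from .scoring import tree_length
from .trees import Tree

__all__ = ["TempletonResult", "templeton_test", "wilcoxon_signed_rank"]

EXACT_LIMIT = 25


@dataclass
class TempletonResult:
    differences: np.ndarray  # per-character s_i(A) - s_i(B)
    n_nonzero: int
    statistic: float  # signed rank sum: W+ - W-
    w_plus: float
    p_value: float
    indistinguishable: bool
    method: str  # "exact" | "normal"


def _exact_p(ranks2: np.ndarray, w2: int) -> float:
    """Two-sided exact p for the doubled positive-rank sum.

    ranks2 are ranks doubled to integers (average ties give halves).
    Convolves the distribution of sum(ranks2 * sign) over the 2^m
    equally likely sign vectors.
    """
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    lo = dist[: w2 + 1].sum()  # P(W+ <= w)
    hi = dist[w2:].sum()       # P(W+ >= w)
    return float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_signed_rank(d: np.ndarray) -> tuple[float, float, float, str]:
    """Two-sided Wilcoxon signed-rank on nonzero differences.

    Returns (W+, signed statistic W+ - W-, p, method).
    """
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    m = d.size
    if m == 0:
        return 0.0, 0.0, 1.0, "degenerate"
    absd = np.abs(d)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(m)
    sorted_abs = absd[order]
    i = 0
    pos = 1
    while i < m:
        j = i
        while j < m and sorted_abs[j] == sorted_abs[i]:
            j += 1
        ranks[order[i:j]] = (pos + (pos + (j - i) - 1)) / 2.0
        pos += j - i
        i = j
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    stat = w_plus - w_minus
    if m <= EXACT_LIMIT:
        ranks2 = np.round(ranks * 2).astype(int)
        p = _exact_p(ranks2, int(round(w_plus * 2)))
        method = "exact"
    else:
        mean = m * (m + 1) / 4.0
        # variance with tie correction
        _, counts = np.unique(sorted_abs, return_counts=True)
        var = m * (m + 1) * (2 * m + 1) / 24.0 - (counts**3 - counts).sum() / 48.0
        cc = 0.5 * np.sign(w_plus - mean)
        z = (w_plus - mean - cc) / math.sqrt(var)
        p = float(min(1.0, 2.0 * (1.0 - _norm_cdf(abs(z)))))
        method = "normal"
    return w_plus, stat, p, method


def _norm_cdf(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


def templeton_test(tree_a: Tree, tree_b: Tree,
                   matrix: CharacterMatrix) -> TempletonResult:
    """Nonparametric comparison of two topologies on one matrix.

    Swapping the tree arguments negates every difference and the signed
    statistic but leaves the two-sided p unchanged.
    """
    _, sa = tree_length(tree_a, matrix, per_character=True)
    _, sb = tree_length(tree_b, matrix, per_character=True)
    d = (sa - sb).astype(float)
    nonzero = int(np.count_nonzero(d))
    w_plus, stat, p, method = wilcoxon_signed_rank(d)
    return TempletonResult(
        differences=d,
        n_nonzero=nonzero,
        statistic=stat,
        w_plus=w_plus,
        p_value=p,
        indistinguishable=nonzero == 0,
        method=method if nonzero else "degenerate",
    )
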