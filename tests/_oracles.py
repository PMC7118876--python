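"""Independent brute-force oracles used only by the test suite.

Deliberately naive O(n²)/enumeration implementations, kept separate from
the package so they cannot share code paths with what they check.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, sqrt

import numpy as np


def naive_midranks(x) -> list[float]:
    """Midranks by pairwise counting."""
    x = list(x)
    return [1 + sum(v < xi for v in x) + (sum(v == xi for v in x) - 1) / 2 for xi in x]


def naive_spearman(x, y) -> float:
    """Pearson correlation of midranks, computed from first principles."""
    rx, ry = naive_midranks(x), naive_midranks(y)
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def enumerate_wilcoxon_p(group1, group2) -> float:
    """Exact two-sided rank-sum P by enumerating every group assignment.

    Tie-free inputs only: P = 2·min(P(W ≤ w), P(W ≥ w)) over all
    C(n1+n2, n1) equally likely assignments, capped at 1.
    """
    pooled = list(group1) + list(group2)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free input"
    n1 = len(group1)
    ranks = naive_midranks(pooled)
    w_obs = sum(ranks[:n1])
    ws = [sum(ranks[i] for i in idx) for idx in combinations(range(len(pooled)), n1)]
    total = comb(len(pooled), n1)
    lo = sum(w <= w_obs for w in ws) / total
    hi = sum(w >= w_obs for w in ws) / total
    return min(1.0, 2.0 * min(lo, hi))


def enumerate_permanova_p(d2: np.ndarray, n1: int) -> float:
    """Exact PERMANOVA P over all distinct assignments of n1 samples to group 1."""
    n = d2.shape[0]

    def pseudo_f(idx1):
        idx1 = np.asarray(idx1)
        idx2 = np.setdiff1d(np.arange(n), idx1)
        ss_total = d2.sum() / 2.0 / n
        ss_within = (
            d2[np.ix_(idx1, idx1)].sum() / 2.0 / idx1.size
            + d2[np.ix_(idx2, idx2)].sum() / 2.0 / idx2.size
        )
        ss_between = ss_total - ss_within
        if ss_within == 0:
            return np.inf
        return (ss_between / 1.0) / (ss_within / (n - 2))

    f_obs = pseudo_f(np.arange(n1))
    fs = [pseudo_f(list(idx)) for idx in combinations(range(n), n1)]
    return sum(f >= f_obs for f in fs) / len(fs)
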