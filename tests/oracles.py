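"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's own code paths (and scipy shortcuts
where the package already uses scipy), recomputing each statistic from first
principles.
"""

import numpy as np


def brute_force_chi2(table):
    """Sum of (O-E)^2/E over all cells of a contingency table."""
    table = np.asarray(table, dtype=float)
    rowsum = table.sum(axis=1, keepdims=True)
    colsum = table.sum(axis=0, keepdims=True)
    expected = rowsum * colsum / table.sum()
    return ((table - expected) ** 2 / expected).sum()


def brute_force_kruskal(groups):
    """Tie-corrected Kruskal-Wallis H from hand-computed mid-ranks."""
    allvals = np.concatenate(groups)
    n = len(allvals)
    order = np.argsort(allvals, kind="mergesort")
    ranks = np.empty(n)
    s = allvals[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and s[j + 1] == s[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    H = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        H += len(g) * (r.mean() - (n + 1) / 2) ** 2
        start += len(g)
    H *= 12 / (n * (n + 1))
    _, counts = np.unique(allvals, return_counts=True)
    tie = 1 - (counts**3 - counts).sum() / (n**3 - n)
    return H / tie if tie > 0 else 0.0


def brute_force_winsor_bounds(vals, lo_pct, hi_pct):
    """Sort-and-index closest-rank winsorization bounds (lower floor,
    upper ceil)."""
    s = np.sort(np.asarray(vals, dtype=float))
    n = len(s)
    lo = s[int(np.floor(lo_pct / 100 * (n - 1)))]
    hi = s[int(np.ceil(hi_pct / 100 * (n - 1)))]
    return lo, hi
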