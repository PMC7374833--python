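"""Fisher–Jenks natural-breaks classification.

One-dimensional optimal classification minimising the total within-class sum
of squared deviations over contiguous classes of the sorted values.  Solved
exactly by dynamic programming over class counts (Fisher's method); ties are
broken toward the earliest break, so the result is deterministic.
"""

from __future__ import annotations

import numpy as np


def _class_costs(sorted_vals: np.ndarray) -> np.ndarray:
    """cost[i, j] = sum of squared deviations of sorted_vals[i..j] inclusive."""
    n = sorted_vals.size
    s1 = np.concatenate(([0.0], np.cumsum(sorted_vals)))
    s2 = np.concatenate(([0.0], np.cumsum(sorted_vals**2)))
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    cnt = j - i + 1
    seg_sum = s1[j + 1] - s1[i]
    seg_sq = s2[j + 1] - s2[i]
    with np.errstate(invalid="ignore", divide="ignore"):
        cost = seg_sq - seg_sum**2 / cnt
    cost[cnt < 1] = np.inf
    return np.maximum(cost, 0.0)


def fisher_jenks_breaks(values, k: int) -> list[float]:
    """Optimal break values (upper class bounds) for ``k`` classes.

    Returns the ``k - 1`` interior break values: class ``c`` holds the values
    ``breaks[c-1] < v <= breaks[c]`` over the sorted order.  If the data hold
    fewer than ``k`` distinct values the class count falls back to the number
    of distinct values.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("cannot classify an empty collection")
    if not np.all(np.isfinite(vals)):
        raise ValueError("values must be finite")
    if k < 1:
        raise ValueError("k must be >= 1")
    svals = np.sort(vals)
    n_distinct = np.unique(svals).size
    k = min(k, n_distinct)
    if k == 1:
        return []

    n = svals.size
    cost = _class_costs(svals)
    # dp[j] = best cost of classifying svals[:j+1]; bt[m][j] = start of last class
    dp = cost[0].copy()
    bt = np.zeros((k, n), dtype=int)
    for m in range(1, k):
        new_dp = np.full(n, np.inf)
        new_bt = np.zeros(n, dtype=int)
        for j in range(m, n):
            # last class starts at i in [m, j]
            cand = dp[m - 1 : j] + cost[m : j + 1, j]
            best = int(np.argmin(cand))  # earliest minimiser -> deterministic
            new_dp[j] = cand[best]
            new_bt[j] = m + best
        dp, bt[m] = new_dp, new_bt

    # backtrack class start indices
    starts = []
    j = n - 1
    for m in range(k - 1, 0, -1):
        i = bt[m][j]
        starts.append(i)
        j = i - 1
    starts.reverse()
    # break value = last value of the preceding class
    return [float(svals[i - 1]) for i in starts]


def jenks_labels(values, k: int, *, highest_is_one: bool = True) -> np.ndarray:
    """Class labels for ``values`` under Fisher–Jenks breaks.

    With ``highest_is_one`` (the convention for access zoning) label 1 is the
    class holding the largest values and the label count grows toward the
    smallest.  Equal values always share a label.
    """
    vals = np.asarray(values, dtype=float)
    breaks = fisher_jenks_breaks(vals, k)
    kk = len(breaks) + 1
    ascending = np.searchsorted(np.asarray(breaks), vals, side="left")  # 0 = lowest class
    if highest_is_one:
        return (kk - ascending).astype(int)
    return (ascending + 1).astype(int)


def total_within_class_ss(sorted_vals: np.ndarray, breaks: list[float]) -> float:
    """Objective value of a given break set (for cross-checking optimality)."""
    svals = np.sort(np.asarray(sorted_vals, dtype=float))
    edges = [-np.inf] + list(breaks) + [np.inf]
    total = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        seg = svals[(svals > lo) & (svals <= hi)]
        if seg.size:
            total += float(np.sum((seg - seg.mean()) ** 2))
    return total
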