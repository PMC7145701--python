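"""Penalized least-squares change-point detection for piecewise-constant
signals (PELT with an L2 segment cost).

Minimises  sum_j cost(segment_j) + beta * (#changepoints)  where
cost(a, b) = sum_{i in [a,b)} (x_i - mean)^2, computed in O(1) from
cumulative sums.  PELT's pruning keeps the search effectively linear for
signals with a bounded density of change points, which is the regime of
single-molecule binding traces.
"""

from __future__ import annotations

import numpy as np

__all__ = ["pelt_mean", "piecewise_means"]


def pelt_mean(x: np.ndarray, penalty: float, min_size: int = 1) -> list[int]:
    """Optimal change-point indices for a piecewise-constant mean model.

    Returns the sorted interior break indices ``b`` such that segments are
    ``x[0:b1], x[b1:b2], ..., x[bk:n]``.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n == 0:
        return []
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def seg_cost(a: int, b: int) -> float:
        d = b - a
        tot = s1[b] - s1[a]
        return (s2[b] - s2[a]) - tot * tot / d

    f = np.full(n + 1, np.inf)
    f[0] = -penalty
    last = np.zeros(n + 1, dtype=int)
    candidates = [0]
    for t in range(min_size, n + 1):
        best, best_s = np.inf, 0
        for s in candidates:
            if t - s < min_size:
                continue
            val = f[s] + seg_cost(s, t) + penalty
            if val < best:
                best, best_s = val, s
        f[t] = best
        last[t] = best_s
        # PELT pruning: drop candidates that can never be optimal again
        candidates = [s for s in candidates
                      if f[s] + seg_cost(s, t) <= f[t]] + [t - min_size + 1]
        candidates = sorted(set(c for c in candidates if 0 <= c <= t))

    breaks = []
    t = n
    while t > 0:
        s = last[t]
        if s > 0:
            breaks.append(s)
        t = s
    return sorted(breaks)


def piecewise_means(x: np.ndarray, breaks: list[int]) -> np.ndarray:
    """Segment means expanded back to the length of ``x``."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    edges = [0] + list(breaks) + [len(x)]
    for a, b in zip(edges[:-1], edges[1:]):
        out[a:b] = x[a:b].mean()
    return out
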