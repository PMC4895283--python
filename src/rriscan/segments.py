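"""Disjoint maximal scoring segments of an additive score vector.

Used by the seed finder (per antidiagonal of the query x reversed-target
comparison) and the tandem-repeat masker (per candidate period).  The
contract is recursive maximal extraction: repeatedly take the maximum-sum
*trimmed* contiguous segment — one in which every proper prefix and proper
suffix has strictly positive sum, so it cannot be shortened without losing
score (trimming also makes the segment set invariant under sequence
reversal); ties go to the smallest start, then the smallest end.  The
segment is removed and the flanks are processed recursively; a branch stops
as soon as its maximum falls below ``min_score``, which is lossless because
every subsegment sum is bounded by the branch maximum.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np


def max_subarray(scores: Sequence[float], lo: int, hi: int) -> Tuple[float, int, int]:
    """Maximum-sum trimmed segment of scores[lo:hi] (Kadane).

    Returns (sum, start, end).  Restarting on non-positive running sums and
    strict improvement yield exactly the trimmed segment with the smallest
    start (then smallest end) among maxima.  ``hi - lo`` must be positive.
    """
    best_sum = -np.inf
    best = (lo, lo + 1)
    cur = 0.0
    cur_start = lo
    for j in range(lo, hi):
        if cur <= 0.0:
            cur = 0.0
            cur_start = j
        cur += scores[j]
        if cur > best_sum:
            best_sum = cur
            best = (cur_start, j + 1)
    return best_sum, best[0], best[1]


def maximal_segments(
    scores: Sequence[float], min_score: float
) -> List[Tuple[int, int, float]]:
    """All disjoint maximal segments with sum >= ``min_score``, sorted by start."""
    n = len(scores)
    out: List[Tuple[int, int, float]] = []
    stack = [(0, n)]
    while stack:
        lo, hi = stack.pop()
        if hi - lo <= 0:
            continue
        s, a, b = max_subarray(scores, lo, hi)
        if s < min_score:
            continue
        out.append((a, b, s))
        stack.append((lo, a))
        stack.append((b, hi))
    out.sort()
    return out


def has_segment_above(scores: np.ndarray, min_score: float) -> bool:
    """Vectorized test: does any contiguous segment reach ``min_score``?"""
    cs = np.concatenate(([0.0], np.cumsum(scores, dtype=np.float64)))
    running_min = np.minimum.accumulate(cs[:-1])
    return bool(np.max(cs[1:] - running_min) >= min_score)
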