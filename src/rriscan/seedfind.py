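"""Gapless reverse-complement seed search (Step 3).

A seed match aligns a query segment against the *reverse complement* of a
target segment with no gaps: query positions increase while target positions
decrease.  Each aligned column scores +1 for a Watson-Crick pair (A-U, C-G)
and -1 otherwise (G-U, mismatches, N, and soft-masked positions).  All
disjoint maximal scoring segments with score >= the seed threshold are
reported; with the +/-1 scoring a score of s implies a length of at least s.

The search is exact: every antidiagonal of the query x target pairing matrix
is scanned (cheap cumulative-sum bound first, maximal-segment extraction on
the survivors).  Candidate seeds are then filtered to those whose footprint
intersects at least one allowed (accessible and unmasked) position on both
molecules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .segments import has_segment_above, maximal_segments
from .seqcore import Region, RnaSequence, allowed_positions

#: WC[a, b] — true when bases (a, b) form a Watson-Crick pair (A=0 C=1 G=2 U=3 N=4)
_WC = np.zeros((5, 5), dtype=bool)
for _a, _b in ((0, 3), (3, 0), (1, 2), (2, 1)):
    _WC[_a, _b] = True


@dataclass(frozen=True)
class SeedMatch:
    """A gapless reverse-complement match between query and target segments.

    Query [q_start, q_end) aligns to the reverse of target [t_start, t_end);
    the two footprints have equal length and ``score`` = (#WC columns) -
    (#non-WC columns).
    """

    query_id: str
    target_id: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    score: int

    def __post_init__(self) -> None:
        if (self.q_end - self.q_start) != (self.t_end - self.t_start):
            raise ValueError("seed footprints must have equal length (gapless)")

    @property
    def length(self) -> int:
        return self.q_end - self.q_start


def seed_score(query: RnaSequence, target: RnaSequence, seed: SeedMatch) -> int:
    """Recompute a seed's score from residues and mask flags."""
    qc, tc = query.codes(), target.codes()
    total = 0
    for k in range(seed.length):
        qi = seed.q_start + k
        tj = seed.t_end - 1 - k
        ok = _WC[qc[qi], tc[tj]] and not query.mask[qi] and not target.mask[tj]
        total += 1 if ok else -1
    return total


def find_seeds(
    query: RnaSequence,
    target: RnaSequence,
    s_thresh: int,
    q_regions: Optional[Sequence[Region]] = None,
    t_regions: Optional[Sequence[Region]] = None,
) -> List[SeedMatch]:
    """All seed matches with score >= ``s_thresh`` touching allowed regions.

    ``q_regions``/``t_regions`` are the accessible regions from Step 1
    (``None`` = everything accessible); masked positions are taken from the
    sequences themselves.  A seed is kept when its query footprint and its
    target footprint each share >= 1 position with an allowed region.
    """
    if s_thresh < 1:
        raise ValueError("seed threshold must be >= 1")
    lq, lt = len(query), len(target)
    if lq == 0 or lt == 0:
        return []

    q_allowed = allowed_positions(lq, q_regions, query.mask)
    t_allowed = allowed_positions(lt, t_regions, target.mask)
    if not q_allowed.any() or not t_allowed.any():
        return []

    qc, tc = query.codes(), target.codes()
    paired = _WC[qc[:, None], tc[None, :]]
    paired &= ~query.mask[:, None]
    paired &= ~target.mask[None, :]
    scores = np.where(paired, 1.0, -1.0)

    seeds: List[SeedMatch] = []
    # column (qi, tj) pairs with its successor (qi+1, tj-1): antidiagonal qi+tj
    for d in range(lq + lt - 1):
        qi_lo = max(0, d - lt + 1)
        qi_hi = min(lq - 1, d)
        diag = scores[qi_lo : qi_hi + 1, :][
            np.arange(qi_hi - qi_lo + 1), d - np.arange(qi_lo, qi_hi + 1)
        ]
        if len(diag) < s_thresh or not has_segment_above(diag, s_thresh):
            continue
        for a, b, s in maximal_segments(diag, float(s_thresh)):
            q_start = qi_lo + a
            q_end = qi_lo + b
            t_end = d - q_start + 1
            t_start = d - (q_end - 1)
            if not q_allowed[q_start:q_end].any():
                continue
            if not t_allowed[t_start:t_end].any():
                continue
            seeds.append(
                SeedMatch(
                    query_id=query.id,
                    target_id=target.id,
                    q_start=q_start,
                    q_end=q_end,
                    t_start=t_start,
                    t_end=t_end,
                    score=int(round(s)),
                )
            )
    seeds.sort(key=lambda m: (m.q_start, m.t_start, m.q_end))
    return seeds
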