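"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by a mechanism different from the
production code path: exhaustive enumeration, quadratic scans, or direct
pairwise counting.  They are deliberately slow and only run at tiny sizes.
"""

from __future__ import annotations

import math
from typing import List, Optional, Sequence, Tuple

from rriscan.energy import EnergyModel, PAIR_TYPES, enumerate_structures, structure_energy
from rriscan.seqcore import Region, RnaSequence


def boltzmann_sum_enumeration(
    seq: str, model: EnergyModel, constraint: Optional[Region] = None
) -> float:
    """Partition function as an explicit sum over enumerated structures."""
    rt = model.rt
    return sum(
        math.exp(-structure_energy(seq, s, model) / rt)
        for s in enumerate_structures(seq, model, constraint)
    )


def accessibility_enumeration(seq: str, start: int, end: int, model: EnergyModel) -> float:
    """Opening energy of [start, end) from enumerated Boltzmann sums."""
    z = boltzmann_sum_enumeration(seq, model)
    zc = boltzmann_sum_enumeration(seq, model, Region("x", start, end))
    return -model.rt * math.log(zc / z)


def quadratic_max_subarray(scores: Sequence[float], lo: int, hi: int):
    """Max-sum *trimmed* segment by full O(n^2) enumeration.

    A trimmed segment has strictly positive sums for every proper prefix and
    proper suffix (it cannot be shortened without losing score); ties are
    resolved to the smallest start, then the smallest end.
    """
    best = None
    for a in range(lo, hi):
        for b in range(a + 1, hi + 1):
            prefix = [0.0]
            for x in scores[a:b]:
                prefix.append(prefix[-1] + x)
            total = prefix[-1]
            inner = prefix[1:-1]
            if any(s <= 0 for s in inner) or any(total - s <= 0 for s in inner):
                continue
            if best is None or total > best[0] + 1e-12:
                best = (total, a, b)
    return best


def maximal_segments_bruteforce(scores: Sequence[float], min_score: float):
    """Disjoint maximal segments via recursive quadratic extraction."""
    out = []
    stack = [(0, len(scores))]
    while stack:
        lo, hi = stack.pop()
        if hi <= lo:
            continue
        found = quadratic_max_subarray(scores, lo, hi)
        if found is None or found[0] < min_score:
            continue
        s, a, b = found
        out.append((a, b, s))
        stack.append((lo, a))
        stack.append((b, hi))
    return sorted(out)


def seed_scan_bruteforce(
    query: RnaSequence, target: RnaSequence, s_thresh: int
) -> List[Tuple[int, int, int, int, int]]:
    """All seeds (q_start, q_end, t_start, t_end, score) by diagonal brute force.

    Full regions, no masking assumed relevant beyond the mask flags carried
    by the sequences themselves.
    """
    wc = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
    lq, lt = len(query), len(target)
    seeds = []
    for d in range(lq + lt - 1):
        cols = []
        for qi in range(max(0, d - lt + 1), min(lq - 1, d) + 1):
            tj = d - qi
            hit = (
                (query.residues[qi], target.residues[tj]) in wc
                and not query.mask[qi]
                and not target.mask[tj]
            )
            cols.append((qi, tj, 1.0 if hit else -1.0))
        scores = [c[2] for c in cols]
        for a, b, s in maximal_segments_bruteforce(scores, float(s_thresh)):
            q_start, q_end = cols[a][0], cols[b - 1][0] + 1
            t_start, t_end = cols[b - 1][1], cols[a][1] + 1
            seeds.append((q_start, q_end, t_start, t_end, int(round(s))))
    return sorted(seeds)


def duplex_enumeration_min_eint(
    query: RnaSequence,
    target: RnaSequence,
    q_window: Region,
    t_window: Region,
    model: EnergyModel,
    q_access,
    t_access,
) -> Optional[float]:
    """Minimum E_int by exhaustive DFS over all monotone duplex structures.

    Chains of intermolecular pairs with strictly increasing query index,
    strictly decreasing target index, bounded interior loops; energy =
    duplex_init + stacks/loops + opening energies of the base-paired spans.
    Returns None when no structure with negative E_int exists.
    """
    allowed = set(PAIR_TYPES)
    stacks = model.stack_energies
    init, max_loop = model.duplex_init, model.max_loop
    qres, tres = query.residues, target.residues
    cells = [
        (i, j)
        for i in range(q_window.start, q_window.end)
        for j in range(t_window.start, t_window.end)
        if qres[i] + tres[j] in allowed
    ]
    best: Optional[float] = None

    def hybrid_energy(chain) -> float:
        e = init
        for (a, b), (c, d) in zip(chain, chain[1:]):
            dq, dt = c - a, b - d
            if dq == 1 and dt == 1:
                e += stacks[(qres[a] + tres[b], qres[c] + tres[d])]
            else:
                e += model.loop_penalty((dq - 1) + (dt - 1))
        return e

    def extend(chain) -> None:
        nonlocal best
        qi, tj = chain[-1]
        e = (
            hybrid_energy(chain)
            + q_access.span_energy(chain[0][0], qi + 1)
            + t_access.span_energy(tj, chain[0][1] + 1)
        )
        if best is None or e < best:
            best = e
        for c, d in cells:
            if c > qi and d < tj and (c - qi - 1) + (tj - d - 1) <= max_loop:
                extend(chain + [(c, d)])

    for cell in cells:
        extend([cell])
    if best is None or best >= 0.0:
        return None
    return best


def auc_pairwise(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """AUC by direct enumeration of positive x negative pairs (ties = 1/2)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p < n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def ntp_recount(rankings, truth_pairs, k: int) -> int:
    """Independent nTP-at-rank recount from raw pairs."""
    total = 0
    for q, ordered in rankings.items():
        for t in list(ordered)[:k]:
            if (q, t) in truth_pairs:
                total += 1
    return total
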