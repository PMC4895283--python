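"""Local interaction energies around seed matches (Step 4).

For each seed, windows of w nucleotides up- and downstream are cut from both
molecules and the minimum *interaction energy* is computed:

    E_int = E_hybrid + ED_query + ED_target

where E_hybrid is the energy of an intermolecular duplex (initiation +
stacking + interior-loop penalties; no intramolecular pairs inside the
windows) and each ED term is the opening energy of exactly the residue span
covered by hybrid pairs on that molecule, taken from the full-length parent
sequence's accessibility (constrained/unconstrained partition-function
ratio).  Interactions whose optimal E_int is >= 0 carry no signal and are
discarded.

The minimization is exact over all duplex structures in the windows.  Since
the ED terms depend on both end pairs, a plain right-anchored DP is only a
heuristic; exactness is restored by branch-and-bound over the duplex's first
pair: opening energies are monotone under span inclusion, so
``E_hybrid_best(start) + ED(start-only spans)`` lower-bounds every duplex
with that first pair.  Starts are explored in lower-bound order against an
incumbent from the heuristic DP and pruned once bounds cross.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ._kernels import build_duplex_graph, duplex_branch_and_bound
from .accessibility import AccessibilityCalculator
from .energy import EnergyModel
from .seedfind import SeedMatch
from .seqcore import Region, RnaSequence


@dataclass(frozen=True)
class LocalInteraction:
    """One predicted local RNA-RNA interaction.

    ``hybrid_pairs`` holds intermolecular pairs (query index, target index)
    in parent coordinates, query indices strictly increasing and target
    indices strictly decreasing; ``q_site``/``t_site`` are the spans actually
    base-paired.  ``e_int == e_hybrid + ed_query + ed_target``.
    """

    query_id: str
    target_id: str
    q_site: Region
    t_site: Region
    hybrid_pairs: Tuple[Tuple[int, int], ...]
    e_hybrid: float
    ed_query: float
    ed_target: float
    e_int: float

    def dot_bracket(self) -> str:
        """Two-strand dot-bracket of the hybrid, query & target both 5'->3'."""
        q = ["." for _ in range(len(self.q_site))]
        t = ["." for _ in range(len(self.t_site))]
        for qi, tj in self.hybrid_pairs:
            q[qi - self.q_site.start] = "("
            t[tj - self.t_site.start] = ")"
        return "".join(q) + "&" + "".join(t)


def extend_window(seed: SeedMatch, w: int, q_len: int, t_len: int) -> Tuple[Region, Region]:
    """Windows of w nt up/downstream of the seed, clipped at sequence ends."""
    if w < 0:
        raise ValueError("w must be >= 0")
    q_win = Region(seed.query_id, max(0, seed.q_start - w), min(q_len, seed.q_end + w))
    t_win = Region(seed.target_id, max(0, seed.t_start - w), min(t_len, seed.t_end + w))
    return q_win, t_win


def min_interaction_energy(
    query: RnaSequence,
    target: RnaSequence,
    q_window: Region,
    t_window: Region,
    model: EnergyModel,
    q_access: AccessibilityCalculator,
    t_access: AccessibilityCalculator,
) -> Optional[LocalInteraction]:
    """Exact minimum-E_int interaction between two windows, or None.

    Returns None when no allowed duplex pair exists in the windows or when
    the optimum is non-negative.
    """
    q0, q1 = q_window.start, q_window.end
    t0, t1 = t_window.start, t_window.end
    if q1 - q0 <= 0 or t1 - t0 <= 0:
        raise ValueError("windows must be non-empty")
    qc = query.codes()[q0:q1]
    tc = target.codes()[t0:t1]
    P = model.duplex_pair_index()[qc[:, None], tc[None, :]]
    if not (P >= 0).any():
        return None

    m, n = P.shape
    iq = np.arange(m)
    it = np.arange(n)
    # inclusive-span opening energies of window spans, from the parents
    ed_q = np.ascontiguousarray(q_access.span_ed[q0 + iq[:, None], q0 + iq[None, :] + 1])
    ed_t = np.ascontiguousarray(t_access.span_ed[t0 + it[:, None], t0 + it[None, :] + 1])
    S6 = model.stack_matrix()
    init, max_loop = model.duplex_init, model.max_loop

    qi_arr, tj_arr, _, indptr, pred, cost = build_duplex_graph(
        P, S6, model.loop_open, model.loop_coef, max_loop
    )
    best, start, end, parent = duplex_branch_and_bound(
        len(qi_arr), indptr, pred, cost, qi_arr, tj_arr, init, ed_q, ed_t
    )
    if start < 0 or best >= 0.0:
        return None

    pairs: List[Tuple[int, int]] = []
    c = end
    while True:
        pairs.append((q0 + int(qi_arr[c]), t0 + int(tj_arr[c])))
        if int(parent[c]) == c:
            break
        c = int(parent[c])
    pairs.reverse()

    sa, sb = int(qi_arr[start]), int(tj_arr[start])
    ea, eb = int(qi_arr[end]), int(tj_arr[end])
    ed_query = float(ed_q[sa, ea])
    ed_target = float(ed_t[eb, sb])
    e_int = float(best)
    return LocalInteraction(
        query_id=query.id,
        target_id=target.id,
        q_site=Region(query.id, q0 + sa, q0 + ea + 1),
        t_site=Region(target.id, t0 + eb, t0 + sb + 1),
        hybrid_pairs=tuple(pairs),
        e_hybrid=e_int - ed_query - ed_target,
        ed_query=ed_query,
        ed_target=ed_target,
        e_int=e_int,
    )


def deduplicate_interactions(interactions: Sequence[LocalInteraction]) -> List[LocalInteraction]:
    """Overlap-resolve interactions of one (query, target) pair.

    Interactions whose query *and* target sites both overlap a better
    (lower-E_int) interaction's sites are dropped; output is sorted by
    ascending e_int with (q_start, t_start) tie-breaks.
    """
    ordered = sorted(
        interactions, key=lambda x: (x.e_int, x.q_site.start, x.t_site.start)
    )
    kept: List[LocalInteraction] = []
    for cand in ordered:
        redundant = any(
            cand.q_site.overlaps(k.q_site) and cand.t_site.overlaps(k.t_site)
            for k in kept
        )
        if not redundant:
            kept.append(cand)
    return kept
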