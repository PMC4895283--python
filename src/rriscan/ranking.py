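"""Per-pair scores and per-query target ranking (Step 5).

Each (query, target) pair with at least one surviving local interaction gets
two scores:

* MinEnergy — the single most stable interaction's E_int; suited to short
  queries where one dominant site drives the biology.
* SumEnergy — the sum of local interaction energies strictly below a cutoff
  x (default -16 kcal/mol); suited to long RNAs with several strong sites.
  Pairs with no interaction below x score 0 and rank after all pairs with a
  negative sum.

Targets of one query are ranked ascending by the chosen score (more negative
is better, rank 1 is best) with lexicographic target-id tie-breaks, so
rankings are total and deterministic.  Scores are computed on the
deduplicated interaction list to avoid double-counting one physical site
found via several seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Sequence, Tuple

from .hybridize import LocalInteraction

DEFAULT_SUM_CUTOFF = -16.0


@dataclass(frozen=True)
class RankedPair:
    """A (query, target) pair with its scores and per-method ranks."""

    query_id: str
    target_id: str
    min_energy: float
    sum_energy: float
    n_interactions: int
    rank_min: int = 0
    rank_sum: int = 0


def min_energy(interactions: Sequence[LocalInteraction]) -> float:
    """MinEnergy score: minimum E_int (list must be non-empty)."""
    if not interactions:
        raise ValueError("pair without interactions should not have been emitted")
    return min(x.e_int for x in interactions)


def sum_energy(interactions: Sequence[LocalInteraction], x: float = DEFAULT_SUM_CUTOFF) -> float:
    """SumEnergy score: sum of E_int values strictly below ``x`` (0.0 if none)."""
    return float(sum(e.e_int for e in interactions if e.e_int < x))


def score_pairs(
    by_pair: Dict[Tuple[str, str], Sequence[LocalInteraction]],
    x: float = DEFAULT_SUM_CUTOFF,
) -> List[RankedPair]:
    """Score every pair's deduplicated interaction list (ranks unset)."""
    return [
        RankedPair(
            query_id=q,
            target_id=t,
            min_energy=min_energy(inters),
            sum_energy=sum_energy(inters, x),
            n_interactions=len(inters),
        )
        for (q, t), inters in by_pair.items()
    ]


def rank_targets(pairs: Sequence[RankedPair], method: str) -> List[RankedPair]:
    """Rank one query's targets by ``method`` ('min' or 'sum').

    Ascending score (more negative = better = rank 1), ties broken
    lexicographically by target id.  Returns copies with the corresponding
    rank field filled in, in rank order.
    """
    if method not in ("min", "sum"):
        raise ValueError("method must be 'min' or 'sum'")
    if len({p.query_id for p in pairs}) > 1:
        raise ValueError("rank_targets expects pairs of a single query")
    key = (lambda p: (p.min_energy, p.target_id)) if method == "min" else (
        lambda p: (p.sum_energy, p.target_id)
    )
    field = "rank_min" if method == "min" else "rank_sum"
    return [
        replace(p, **{field: i}) for i, p in enumerate(sorted(pairs, key=key), start=1)
    ]


def rank_all(pairs: Iterable[RankedPair]) -> List[RankedPair]:
    """Assign both rank_min and rank_sum within each query."""
    by_query: Dict[str, List[RankedPair]] = {}
    for p in pairs:
        by_query.setdefault(p.query_id, []).append(p)
    out: List[RankedPair] = []
    for q in sorted(by_query):
        ranked_min = {p.target_id: p.rank_min for p in rank_targets(by_query[q], "min")}
        for p in rank_targets(by_query[q], "sum"):
            out.append(replace(p, rank_min=ranked_min[p.target_id]))
    out.sort(key=lambda p: (p.query_id, p.rank_min))
    return out


def ranking_by_query(
    pairs: Sequence[RankedPair], method: str = "min"
) -> Dict[str, List[str]]:
    """Ordered target-id lists per query under the chosen method."""
    attr = "rank_min" if method == "min" else "rank_sum"
    if method not in ("min", "sum"):
        raise ValueError("method must be 'min' or 'sum'")
    by_query: Dict[str, List[RankedPair]] = {}
    for p in pairs:
        by_query.setdefault(p.query_id, []).append(p)
    return {
        q: [p.target_id for p in sorted(ps, key=lambda p: getattr(p, attr))]
        for q, ps in by_query.items()
    }
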