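"""Evaluation harness: nTP-at-rank, AUC-ROC, and the parameter sweep.

Evaluation follows the competing-candidate design: for each query, all
targets in the target set compete, the known interacting targets are the
positives, and everything else is a negative.  nTP-at-rank counts known
targets recovered within each query's top k, summed over queries; AUC-ROC is
the Mann-Whitney probability that a random positive outscores (has a more
negative energy than) a random negative, ties counting one half.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass(frozen=True)
class TruthTable:
    """Known interacting (query_id, target_id) pairs."""

    pairs: frozenset

    @staticmethod
    def from_pairs(pairs: Iterable[Tuple[str, str]]) -> "TruthTable":
        return TruthTable(frozenset(tuple(p) for p in pairs))

    @staticmethod
    def read_tsv(path: Union[str, Path]) -> "TruthTable":
        out = set()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            q, t = line.split("\t")[:2]
            out.add((q, t))
        return TruthTable(frozenset(out))

    def targets_of(self, query_id: str) -> Set[str]:
        return {t for q, t in self.pairs if q == query_id}

    def validate_ids(self, query_ids: Iterable[str], target_ids: Iterable[str]) -> None:
        qs, ts = set(query_ids), set(target_ids)
        for q, t in self.pairs:
            if q not in qs or t not in ts:
                raise ValueError(f"truth pair ({q}, {t}) refers to unknown sequences")

    def __len__(self) -> int:
        return len(self.pairs)


def ntp_at_rank(
    rankings: Mapping[str, Sequence[str]], truth: TruthTable, k: int
) -> int:
    """Number of true positives within each query's top ``k``, summed."""
    if k < 0:
        raise ValueError("k must be >= 0")
    total = 0
    for query_id, ordered in rankings.items():
        true_targets = truth.targets_of(query_id)
        total += sum(1 for t in ordered[:k] if t in true_targets)
    return total


def auc_roc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """AUC-ROC for energy-like scores (lower = better), Mann-Whitney form.

    Probability that a uniformly random positive has a lower score than a
    uniformly random negative, with ties counting 1/2.  Raises on
    single-class input.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = rankdata(scores)  # ascending, ties averaged
    r_pos = float(ranks[labels].sum())
    u_pos_worse = r_pos - n_pos * (n_pos + 1) / 2.0
    return 1.0 - u_pos_worse / (n_pos * n_neg)


def per_query_auc(
    pairs,  # Sequence[ranking.RankedPair]
    truth: TruthTable,
    method: str = "min",
) -> Dict[str, float]:
    """AUC-ROC per query over its scored targets (skips one-class queries)."""
    attr = "min_energy" if method == "min" else "sum_energy"
    by_query: Dict[str, List] = {}
    for p in pairs:
        by_query.setdefault(p.query_id, []).append(p)
    out: Dict[str, float] = {}
    for q, ps in by_query.items():
        true_targets = truth.targets_of(q)
        labels = [p.target_id in true_targets for p in ps]
        if any(labels) and not all(labels):
            out[q] = auc_roc([getattr(p, attr) for p in ps], labels)
    return out


def parameter_sweep(
    t_values: Sequence[float],
    s_values: Sequence[int],
    w_values: Sequence[int],
    queries,
    targets,
    truth: TruthTable,
    ranks: Sequence[int] = (1, 2, 5, 10),
    method: str = "min",
    base_config=None,
) -> pd.DataFrame:
    """Full pipeline run per (t, s, w) grid point.

    Returns one row per grid point with candidate counts, nTP at the
    requested ranks, and wall-clock runtime.  Include ``t=inf`` in
    ``t_values`` to measure the no-accessibility-filter baseline.
    """
    from .pipeline import PipelineConfig, run_pipeline
    from .ranking import ranking_by_query

    rows = []
    for t in t_values:
        for s in s_values:
            for w in w_values:
                config = PipelineConfig(
                    **{
                        **(base_config.__dict__ if base_config else {}),
                        "t": float(t),
                        "seed_score": int(s),
                        "w": int(w),
                    }
                )
                started = time.perf_counter()
                result = run_pipeline(queries, targets, config)
                runtime = time.perf_counter() - started
                rankings = ranking_by_query(result.ranked_pairs, method)
                row = {
                    "t": float(t),
                    "s": int(s),
                    "w": int(w),
                    "n_seeds": result.counts["seeds"],
                    "n_interactions": result.counts["interactions"],
                    "n_pairs": result.counts["ranked_pairs"],
                    "runtime_s": runtime,
                }
                for k in ranks:
                    row[f"ntp_at_{k}"] = ntp_at_rank(rankings, truth, k)
                rows.append(row)
    return pd.DataFrame(rows)


def count_seeds_at_sites(
    seeds,  # Sequence[seedfind.SeedMatch]
    sites,  # Sequence[synthetic.PlantedSite]
) -> Dict[Tuple[str, str], int]:
    """Surviving planted-signal seeds per planted site.

    Counts seeds of the site's own query whose target footprint overlaps the
    site; keyed by (target_id, kind).  Used to quantify how accessibility
    filtering suppresses seeds at intramolecularly occluded sites.
    """
    counts: Dict[Tuple[str, str], int] = {}
    for site in sites:
        n = sum(
            1
            for s in seeds
            if s.target_id == site.target_id
            and s.query_id == site.query_id
            and s.t_start < site.end
            and site.start < s.t_end
        )
        counts[(site.target_id, site.kind)] = counts.get((site.target_id, site.kind), 0) + n
    return counts
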