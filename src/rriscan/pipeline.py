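"""End-to-end pipeline: accessibility screen -> repeat mask -> seed search ->
local interaction energies -> per-query ranking.

The three screening parameters are ``t`` (accessibility threshold,
kcal/mol), ``seed_score`` (minimum gapless seed score, with ``access_len``
the screening window length) and ``w`` (flank length around each seed for
energy evaluation); ``x`` is the SumEnergy cutoff.  Defaults are the trained
operating point t=4.3 kcal/mol, access_len=8, seed_score=8, w=20,
x=-16 kcal/mol, so a bare invocation reproduces it.

Query/target asymmetry is preserved (rankings are per query over targets)
even though interaction energies themselves are symmetric, and
self-interaction pairs (same id in both sets) are reported, not suppressed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd
import yaml

from .accessibility import AccessibilityCalculator, accessible_regions
from .energy import EnergyModel, load_pair_energies, load_stack_energies
from .hybridize import (
    LocalInteraction,
    deduplicate_interactions,
    extend_window,
    min_interaction_energy,
)
from .ranking import RankedPair, rank_all, score_pairs
from .repeat_mask import (
    DEFAULT_MAX_PERIOD,
    DEFAULT_MIN_IDENTITY,
    DEFAULT_MIN_TOTAL_LEN,
    mask_tandem_repeats,
)
from .seedfind import SeedMatch, find_seeds
from .seqcore import Region, RnaSequence, read_fasta

logger = logging.getLogger("rriscan")


@dataclass
class PipelineConfig:
    """Pipeline parameters (flat key-value config file compatible)."""

    t: float = 4.3
    access_len: int = 8
    seed_score: int = 8
    w: int = 20
    x: float = -16.0
    mask_max_period: int = DEFAULT_MAX_PERIOD
    mask_min_total_len: int = DEFAULT_MIN_TOTAL_LEN
    mask_min_identity: float = DEFAULT_MIN_IDENTITY
    pair_energies_path: Optional[str] = None
    stack_energies_path: Optional[str] = None

    def __post_init__(self) -> None:
        self.t = float(self.t)
        if self.access_len < 1 or self.seed_score < 1:
            raise ValueError("access_len and seed_score must be >= 1")
        if self.w < 0:
            raise ValueError("w must be >= 0")

    def energy_model(self) -> EnergyModel:
        return EnergyModel(
            pair_energies=load_pair_energies(self.pair_energies_path),
            stack_energies=load_stack_energies(self.stack_energies_path),
        )

    @staticmethod
    def from_yaml(path: Union[str, Path], **overrides) -> "PipelineConfig":
        """Load a flat key: value YAML document; kwargs override file keys."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a flat key-value mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = set(PipelineConfig.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return PipelineConfig(**data)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


@dataclass
class PipelineResult:
    seeds: List[SeedMatch]
    interactions: List[LocalInteraction]
    ranked_pairs: List[RankedPair]
    counts: Dict[str, float]
    config: PipelineConfig

    def interactions_table(self) -> pd.DataFrame:
        rows = [
            {
                "query_id": x.query_id,
                "target_id": x.target_id,
                "q_start": x.q_site.start,
                "q_end": x.q_site.end,
                "t_start": x.t_site.start,
                "t_end": x.t_site.end,
                "e_hybrid": x.e_hybrid,
                "ed_query": x.ed_query,
                "ed_target": x.ed_target,
                "e_int": x.e_int,
                "hybrid": x.dot_bracket(),
            }
            for x in self.interactions
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "query_id", "target_id", "q_start", "q_end", "t_start",
                "t_end", "e_hybrid", "ed_query", "ed_target", "e_int", "hybrid",
            ],
        )

    def rankings_table(self) -> pd.DataFrame:
        rows = [
            {
                "query_id": p.query_id,
                "target_id": p.target_id,
                "min_energy": p.min_energy,
                "sum_energy": p.sum_energy,
                "n_interactions": p.n_interactions,
                "rank_min": p.rank_min,
                "rank_sum": p.rank_sum,
            }
            for p in self.ranked_pairs
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "query_id", "target_id", "min_energy", "sum_energy",
                "n_interactions", "rank_min", "rank_sum",
            ],
        )


def _as_sequences(source) -> List[RnaSequence]:
    if isinstance(source, (str, Path)):
        return read_fasta(source)
    return list(source)


def run_pipeline(
    queries,
    targets,
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Run Steps 1-5 on the given query/target sets (FASTA paths or lists)."""
    config = config or PipelineConfig()
    model = config.energy_model()
    queries = _as_sequences(queries)
    targets = _as_sequences(targets)
    logger.info("pipeline start: %d queries x %d targets", len(queries), len(targets))

    # Step 2: tandem-repeat soft masking (before seeding; coordinates kept)
    queries = [
        mask_tandem_repeats(
            s, config.mask_max_period, config.mask_min_total_len, config.mask_min_identity
        )
        for s in queries
    ]
    targets = [
        mask_tandem_repeats(
            s, config.mask_max_period, config.mask_min_total_len, config.mask_min_identity
        )
        for s in targets
    ]
    n_pos = sum(len(s) for s in queries) + sum(len(s) for s in targets)
    n_masked = sum(int(s.mask.sum()) for s in queries) + sum(
        int(s.mask.sum()) for s in targets
    )
    logger.info("step 2: masked %d/%d positions", n_masked, n_pos)

    # Step 1: accessibility profiles and accessible regions.
    # Calculators are cached by residue string (shared query/target entries
    # and self-pairs fold onto one computation) and reused in Step 4 for the
    # site-opening penalties.
    calculators: Dict[str, AccessibilityCalculator] = {}

    def calculator(seq: RnaSequence) -> AccessibilityCalculator:
        calc = calculators.get(seq.residues)
        if calc is None:
            calc = AccessibilityCalculator(seq, model)
            calculators[seq.residues] = calc
        return calc

    def regions_of(seq: RnaSequence) -> List[Region]:
        profile = calculator(seq).profile(config.access_len)
        profile.seq_id = seq.id
        return accessible_regions(profile, config.t)

    q_regions = {s.id: regions_of(s) for s in queries}
    t_regions = {s.id: regions_of(s) for s in targets}
    acc_len = sum(sum(len(r) for r in rs) for rs in q_regions.values()) + sum(
        sum(len(r) for r in rs) for rs in t_regions.values()
    )
    logger.info(
        "step 1: accessible %d/%d positions (t=%s, access_len=%d)",
        acc_len, n_pos, config.t, config.access_len,
    )

    # Step 3: gapless reverse-complement seeds within allowed regions
    seeds: List[SeedMatch] = []
    for q in queries:
        for t in targets:
            seeds.extend(
                find_seeds(q, t, config.seed_score, q_regions[q.id], t_regions[t.id])
            )
    logger.info("step 3: %d seeds (seed_score>=%d)", len(seeds), config.seed_score)

    # Step 4: minimum interaction energy on +/-w windows around each seed
    q_by_id = {s.id: s for s in queries}
    t_by_id = {s.id: s for s in targets}
    window_cache: Dict[Tuple[str, str, int, int, int, int], Optional[LocalInteraction]] = {}
    per_pair: Dict[Tuple[str, str], List[LocalInteraction]] = {}
    for seed in seeds:
        q = q_by_id[seed.query_id]
        t = t_by_id[seed.target_id]
        q_win, t_win = extend_window(seed, config.w, len(q), len(t))
        key = (seed.query_id, seed.target_id, q_win.start, q_win.end, t_win.start, t_win.end)
        if key in window_cache:
            continue
        window_cache[key] = min_interaction_energy(
            q, t, q_win, t_win, model, calculator(q), calculator(t)
        )
    for (qid, tid, *_), inter in window_cache.items():
        if inter is not None:
            per_pair.setdefault((qid, tid), []).append(inter)
    n_windows = len(window_cache)

    per_pair = {k: deduplicate_interactions(v) for k, v in per_pair.items()}
    interactions = [x for v in per_pair.values() for x in v]
    interactions.sort(key=lambda x: (x.query_id, x.target_id, x.e_int, x.q_site.start))
    logger.info(
        "step 4: %d windows -> %d local interactions (w=%d)",
        n_windows, len(interactions), config.w,
    )

    # Step 5: MinEnergy / SumEnergy scores and per-query ranks
    ranked = rank_all(score_pairs(per_pair, config.x))
    logger.info("step 5: %d ranked (query, target) pairs (x=%s)", len(ranked), config.x)

    counts = {
        "queries": len(queries),
        "targets": len(targets),
        "positions": n_pos,
        "masked_positions": n_masked,
        "accessible_positions": acc_len,
        "seeds": len(seeds),
        "windows": n_windows,
        "interactions": len(interactions),
        "ranked_pairs": len(ranked),
    }
    return PipelineResult(
        seeds=seeds,
        interactions=interactions,
        ranked_pairs=ranked,
        counts=counts,
        config=config,
    )
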