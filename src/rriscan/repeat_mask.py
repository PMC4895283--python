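"""Tandem-repeat soft-masking (Step 2).

A deterministic, testable stand-in for probabilistic repeat maskers: a
region is masked when, for some fixed period p <= max_period, residues match
the residue p positions earlier over a run of at least ``min_total_len``
residues (template prefix included) with identity >= ``min_identity`` among
the comparable positions.  Candidate runs per period are located as maximal
scoring segments under the scoring (1 - min_identity) per match and
-min_identity per mismatch, so any segment with positive sum exceeds the
identity floor; each candidate is then re-checked explicitly.  A run may
never fall more than a fixed X-drop below its running score peak, so two
repeat tracts cannot bridge across a non-repetitive insert by subsidizing
its mismatches with their own matches.

Masking is *soft*: flagged positions keep their coordinates and are only
excluded from seed matching, not from energy evaluation windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from .segments import maximal_segments
from .seqcore import RnaSequence

DEFAULT_MAX_PERIOD = 50
DEFAULT_MIN_TOTAL_LEN = 20
DEFAULT_MIN_IDENTITY = 0.9
#: X-drop bound: a run is severed where its score falls this far below the
#: running peak, so two repeat tracts cannot bridge across an intervening
#: non-repetitive insert on global identity alone (the insert's mismatches
#: would be subsidized by the flanking matches otherwise)
DEFAULT_MAX_DROP = 4.5


@dataclass(frozen=True)
class MaskedRun:
    """A masked tandem run: [start, end) with its repeat period."""

    seq_id: str
    start: int
    end: int
    period: int


def _xdrop_chunks(scores: np.ndarray, max_drop: float) -> List[tuple]:
    """Split positions where the running sum falls ``max_drop`` below its peak."""
    chunks = []
    start = 0
    peak = running = 0.0
    for idx, sc in enumerate(scores):
        running += sc
        if running > peak:
            peak = running
        elif peak - running > max_drop:
            chunks.append((start, idx + 1))
            start = idx + 1
            peak = running = 0.0
    chunks.append((start, len(scores)))
    return chunks


def find_tandem_runs(
    seq: RnaSequence,
    max_period: int = DEFAULT_MAX_PERIOD,
    min_total_len: int = DEFAULT_MIN_TOTAL_LEN,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_drop: float = DEFAULT_MAX_DROP,
) -> List[MaskedRun]:
    """Locate tandem runs qualifying for masking (see module docstring)."""
    if max_period < 1:
        raise ValueError("max_period must be >= 1")
    n = len(seq)
    res = np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)
    runs: List[MaskedRun] = []
    for p in range(1, min(max_period, n - 1) + 1):
        match = res[p:] == res[:-p]
        if not match.any():
            continue
        scores = np.where(match, 1.0 - min_identity, -min_identity)
        for lo, hi in _xdrop_chunks(scores, max_drop):
            for a0, b0, _ in maximal_segments(scores[lo:hi], 1.0 - min_identity):
                # a, b index the comparable positions p..n-1 (offset by p)
                a, b = lo + a0, lo + b0
                length = (b - a) + p  # run length including the period template
                identity = float(match[a:b].mean())
                # (b - a) >= p demands at least two full copies of the unit,
                # so a chance match at a long period cannot qualify alone
                if length >= min_total_len and (b - a) >= p and identity >= min_identity:
                    runs.append(MaskedRun(seq.id, a, b + p, p))
    return runs


def mask_tandem_repeats(
    seq: RnaSequence,
    max_period: int = DEFAULT_MAX_PERIOD,
    min_total_len: int = DEFAULT_MIN_TOTAL_LEN,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> RnaSequence:
    """Return a copy of ``seq`` with tandem-repeat positions soft-masked.

    Pre-existing mask flags are preserved; the operation is idempotent
    because it depends only on the residues.
    """
    mask = seq.mask.copy()
    for run in find_tandem_runs(seq, max_period, min_total_len, min_identity):
        mask[run.start : run.end] = True
    return RnaSequence(id=seq.id, residues=seq.residues, mask=mask)
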