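"""Windowed accessibility: partition functions and opening energies.

The accessibility of a region r is dE_acc(r) = -RT log P(r), where P(r) is
the Boltzmann probability that every position of r is unpaired:

    P(r) = Zc(r) / Z

with Z the partition function over all nested secondary structures and
Zc(r) the same sum restricted to structures leaving r unpaired.  Opening
energies are always >= 0 and monotone under span inclusion.

:func:`partition_function` exposes the (optionally constrained) inside DP
directly; :class:`AccessibilityCalculator` computes, once per sequence, the
opening energy of *every* span in O(n^3) via the inside/outside algorithm in
``_kernels`` — this backs both the fixed-window screening profile (Step 1)
and the site-opening penalties used during hybridization (Step 4).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

import numpy as np

from . import _kernels
from .energy import EnergyModel, default_model
from .seqcore import Region, RnaSequence, encode, merge_intervals

#: per-nucleotide log rescaling ladder tried until the scaled Z is in range
_LNSIG_LADDER = (0.0, 0.75, 1.5, 2.25)


def _weight_matrices(
    codes: np.ndarray,
    model: EnergyModel,
    lnsig: float,
    forced_unpaired: Optional[Region] = None,
):
    """Scaled pair weights p(i,k) = exp(-E_pair/RT - 2*lnsig) and stack
    Boltzmann factors st(i,k) for pair (i,k) on pair (i+1,k-1)."""
    pm = model.intra_pair_matrix()
    e = pm[codes[:, None], codes[None, :]]
    with np.errstate(over="ignore"):
        p = np.exp(-e / model.rt - 2.0 * lnsig)
    p[~np.isfinite(e)] = 0.0
    n = len(codes)
    ii, kk = np.indices((n, n))
    p[kk - ii <= model.min_loop] = 0.0
    if model.max_pair_span is not None:
        p[kk - ii > model.max_pair_span] = 0.0
    if forced_unpaired is not None:
        if not (0 <= forced_unpaired.start < forced_unpaired.end <= n):
            raise ValueError("constraint region outside sequence")
        p[forced_unpaired.start : forced_unpaired.end, :] = 0.0
        p[:, forced_unpaired.start : forced_unpaired.end] = 0.0
    # stack factor of (i, k) on (i+1, k-1); only read where Zb(i+1,k-1) > 0
    pidx = model.duplex_pair_index()[codes[:, None], codes[None, :]]
    st6 = np.exp(-model.intra_stack_matrix() / model.rt)
    st = np.ones((n, n))
    inner = np.full((n, n), -1, dtype=np.int8)
    inner[: n - 1, 1:] = pidx[1:, : n - 1]
    both = (pidx >= 0) & (inner >= 0)
    st[both] = st6[pidx[both], inner[both]]
    return p, st


def _scaled_inside(
    codes: np.ndarray,
    model: EnergyModel,
    constraint: Optional[Region] = None,
):
    """Run the inside DP, escalating the rescaling factor until in range."""
    for lnsig in _LNSIG_LADDER:
        P, ST = _weight_matrices(codes, model, lnsig, constraint)
        hw = math.exp(-model.helix_init / model.rt)
        Z, Zb = _kernels.inside(P, ST, hw, math.exp(-lnsig), model.min_loop)
        top = Z[0, len(codes)]
        if np.isfinite(top) and 1e-250 < top < 1e250:
            return P, ST, Z, Zb, lnsig
    raise OverflowError(
        "partition function out of double range even after rescaling; "
        "sequence too long/structured for this model"
    )


def _residues(seq: Union[str, RnaSequence]) -> str:
    return seq.residues if isinstance(seq, RnaSequence) else seq


def log_partition_function(
    seq: Union[str, RnaSequence],
    model: Optional[EnergyModel] = None,
    constraint: Optional[Region] = None,
) -> float:
    """log Z over nested structures (optionally with a forced-unpaired region)."""
    residues = _residues(seq)
    if not residues:
        raise ValueError("empty sequence")
    model = model or default_model()
    codes = encode(residues)
    _, _, Z, _, lnsig = _scaled_inside(codes, model, constraint)
    return float(math.log(Z[0, len(codes)]) + len(codes) * lnsig)


def partition_function(
    seq: Union[str, RnaSequence],
    model: Optional[EnergyModel] = None,
    constraint: Optional[Region] = None,
) -> float:
    """Partition function Z >= 1 (the empty structure contributes 1).

    Returns ``inf`` if Z exceeds double range; use
    :func:`log_partition_function` in that regime.
    """
    lz = log_partition_function(seq, model, constraint)
    try:
        return math.exp(lz)
    except OverflowError:
        return math.inf


@dataclass
class AccessibilityProfile:
    """Per-start opening energies for windows of fixed length ``window_len``.

    ``energies[i]`` is dE_acc of the window [i, i + window_len); the list is
    empty when the sequence is shorter than the window.
    """

    seq_id: str
    window_len: int
    energies: np.ndarray

    def __len__(self) -> int:
        return len(self.energies)


class AccessibilityCalculator:
    """Opening energies of every span of one sequence, computed once.

    ``span_energy(a, b)`` returns dE_acc of the half-open span [a, b) of the
    full-length parent sequence; ``profile(s)`` returns the fixed-window
    screening profile.  Backed by the O(n^3) inside/outside span algorithm.
    """

    def __init__(self, seq: Union[str, RnaSequence], model: Optional[EnergyModel] = None):
        residues = _residues(seq)
        if not residues:
            raise ValueError("empty sequence")
        self.seq_id = seq.id if isinstance(seq, RnaSequence) else ""
        self.model = model or default_model()
        codes = encode(residues)
        self.length = len(codes)
        P, ST, Z, Zb, lnsig = _scaled_inside(codes, self.model)
        hw = math.exp(-self.model.helix_init / self.model.rt)
        _, Ob = _kernels.outside(
            P, ST, hw, Z, Zb, math.exp(-lnsig), self.model.min_loop
        )
        self.span_ed = _kernels.span_accessibility(
            P, Z, Ob, hw, self.model.rt, lnsig, self.model.min_loop
        )
        if np.isnan(self.span_ed).any():
            raise FloatingPointError("span accessibility produced NaN")
        self.log_z = float(math.log(Z[0, self.length]) + self.length * lnsig)

    def span_energy(self, start: int, end: int) -> float:
        """dE_acc of span [start, end), kcal/mol (>= 0)."""
        if not (0 <= start < end <= self.length):
            raise ValueError(f"span [{start}, {end}) outside sequence")
        return float(self.span_ed[start, end])

    def profile(self, window_len: int) -> AccessibilityProfile:
        if window_len < 1:
            raise ValueError("window length must be >= 1")
        n_windows = self.length - window_len + 1
        if n_windows <= 0:
            energies = np.zeros(0)
        else:
            idx = np.arange(n_windows)
            energies = self.span_ed[idx, idx + window_len].copy()
        return AccessibilityProfile(self.seq_id, window_len, energies)


def accessibility_profile(
    seq: Union[str, RnaSequence],
    window_len: int,
    model: Optional[EnergyModel] = None,
) -> AccessibilityProfile:
    """dE_acc for every window of ``window_len`` consecutive nucleotides."""
    residues = _residues(seq)
    if window_len >= 1 and len(residues) < window_len:
        seq_id = seq.id if isinstance(seq, RnaSequence) else ""
        return AccessibilityProfile(seq_id, window_len, np.zeros(0))
    return AccessibilityCalculator(seq, model).profile(window_len)


def accessible_regions(profile: AccessibilityProfile, threshold: float) -> List[Region]:
    """Merged regions covered by windows with dE_acc strictly below ``threshold``.

    Every emitted region has length >= the window length; ``threshold=inf``
    yields one region covering the whole profiled range, ``threshold<=0``
    yields none (opening energies are >= 0 and the comparison is strict).
    """
    s = profile.window_len
    passing = np.nonzero(profile.energies < threshold)[0]
    intervals = [(int(i), int(i) + s) for i in passing]
    seq_id = profile.seq_id or "?"
    return [Region(seq_id, a, b) for a, b in merge_intervals(intervals)]


def allowed_from_regions(length: int, regions: Sequence[Region]) -> np.ndarray:
    allowed = np.zeros(length, dtype=bool)
    for r in regions:
        allowed[r.start : r.end] = True
    return allowed
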