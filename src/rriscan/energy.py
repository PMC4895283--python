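"""Thermodynamic model shared by the accessibility and hybridization stages.

Two energy functions live here:

* an *intramolecular* model used for folding partition functions: nested
  secondary structures scored by per-pair energies, a nearest-neighbor
  style stacking term for directly adjacent pairs, and a helix-initiation
  cost charged once per helix.  This cooperative parameterization keeps the
  grammar simple enough to verify against exhaustive structure enumeration
  while reproducing the feature accessibility screening depends on:
  isolated chance pairs are unstable, contiguous helices fold.  Folding is
  local (a maximum pair span), as in windowed accessibility tools.
* an *intermolecular* (duplex) model used for hybridization energies — the
  same stacking table over the six canonical RNA pairs, a duplex initiation
  cost, and an affine penalty (opening constant plus length term) for
  bounded interior loops and bulges.

The tables ship as editable TSV data files; configuration can point to
alternatives, and :class:`EnergyModel` admits non-cooperative variants
(empty stack table, zero helix initiation) for closed-form testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Set, Tuple, Union

import numpy as np

from .seqcore import BASE_INDEX, Region

#: gas constant in kcal/(mol K)
GAS_CONSTANT = 0.0019872
#: physiological temperature in K
DEFAULT_TEMPERATURE = 310.15

PAIR_TYPES = ("CG", "GC", "GU", "UG", "AU", "UA")
PAIR_TYPE_INDEX = {p: i for i, p in enumerate(PAIR_TYPES)}

#: hard ceiling for exhaustive structure enumeration (oracle use only)
DEFAULT_ORACLE_LIMIT = 18


def _data_path(name: str) -> Path:
    return Path(str(resources.files("rriscan").joinpath("data").joinpath(name)))


def load_pair_energies(path: Union[str, Path, None] = None) -> Dict[str, float]:
    """Load intramolecular pair energies from a 2-column TSV."""
    path = _data_path("pair_energies.tsv") if path is None else Path(path)
    table: Dict[str, float] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        pair, energy = line.split("\t")
        if pair not in PAIR_TYPE_INDEX:
            raise ValueError(f"unknown pair type {pair!r} in {path}")
        table[pair] = float(energy)
    return table


def load_stack_energies(path: Union[str, Path, None] = None) -> Dict[Tuple[str, str], float]:
    """Load duplex stacking energies from a 3-column TSV.

    Keys are (pair1, pair2) for consecutive duplex pairs, both written
    query-base first.  The table must satisfy the strand-reversal identity
    ``stack(p1, p2) == stack(rev(p2), rev(p1))`` so that hybridization
    energies do not depend on which molecule is called the query.
    """
    path = _data_path("stack_energies.tsv") if path is None else Path(path)
    table: Dict[Tuple[str, str], float] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        p1, p2, energy = line.split("\t")
        table[(p1, p2)] = float(energy)
    for (p1, p2), e in table.items():
        mirror = (p2[::-1], p1[::-1])
        if mirror not in table or abs(table[mirror] - e) > 1e-9:
            raise ValueError(f"stack table violates strand-reversal symmetry at {(p1, p2)}")
    return table


@dataclass
class EnergyModel:
    """Energy parameters for folding and hybridization.

    Parameters
    ----------
    gas_constant, temperature
        kcal/(mol K) and K; ``RT`` is their product.
    min_loop
        Minimum number of unpaired residues enclosed by an intramolecular
        pair (steric constraint; pair (i, j) requires j - i > min_loop).
    pair_energies
        kcal/mol per intramolecular pair type (a small per-pair term on top
        of stacking and helix initiation; see below).
    intra_stack_energies
        kcal/mol for an intramolecular pair (i, j) stacked on (i+1, j-1);
        defaults to the duplex stacking table.  An empty mapping together
        with helix_init = 0 turns cooperativity off (pair-additive model).
    helix_init
        kcal/mol charged once per intramolecular helix (on its innermost
        pair): the loop-closure entropy that makes isolated chance pairs
        unstable while long contiguous helices remain strongly folded.
    stack_energies
        kcal/mol per adjacent duplex pair-type pair (query-base-first keys).
    duplex_init
        Initiation cost of an intermolecular duplex, kcal/mol.
    loop_open, loop_coef
        Interior-loop/bulge penalty in the duplex:
        ``loop_penalty(k) = loop_open + loop_coef*k`` for total unpaired
        length k >= 1 between consecutive duplex pairs (0 for k = 0).  The
        opening constant reflects the nearest-neighbor scale of loop
        initiation; without it, chains of short helices stitched through
        many cheap loops dominate every window.
    max_loop
        Upper bound on that total unpaired length.
    max_pair_span
        Maximum intramolecular pair span j - i (local folding, as in
        windowed accessibility tools); None = unlimited.
    oracle_limit
        Maximum sequence length accepted by exhaustive enumeration.
    """

    gas_constant: float = GAS_CONSTANT
    temperature: float = DEFAULT_TEMPERATURE
    min_loop: int = 3
    pair_energies: Dict[str, float] = field(default_factory=load_pair_energies)
    stack_energies: Dict[Tuple[str, str], float] = field(default_factory=load_stack_energies)
    intra_stack_energies: Dict[Tuple[str, str], float] = field(
        default_factory=load_stack_energies
    )
    helix_init: float = 4.0
    duplex_init: float = 4.1
    loop_open: float = 4.0
    loop_coef: float = 0.5
    max_loop: int = 15
    max_pair_span: Optional[int] = 60
    oracle_limit: int = DEFAULT_ORACLE_LIMIT

    def __post_init__(self) -> None:
        if self.gas_constant <= 0 or self.temperature <= 0:
            raise ValueError("gas_constant and temperature must be positive")
        if self.min_loop < 3:
            raise ValueError("min_loop must be >= 3")
        if self.max_loop < 0 or self.loop_coef < 0 or self.loop_open < 0:
            raise ValueError("loop parameters must be non-negative")
        if self.max_pair_span is not None and self.max_pair_span <= self.min_loop:
            raise ValueError("max_pair_span must exceed min_loop")

    @property
    def rt(self) -> float:
        """Thermal energy R*T in kcal/mol."""
        return self.gas_constant * self.temperature

    def loop_penalty(self, k: int) -> float:
        """Cost of an interior loop/bulge of total unpaired length ``k``."""
        if k < 0 or k > self.max_loop:
            raise ValueError(f"loop length {k} outside [0, {self.max_loop}]")
        return 0.0 if k == 0 else self.loop_open + self.loop_coef * k

    def pair_allowed(self, i: int, j: int) -> bool:
        """Steric/span constraints for an intramolecular pair (i < j)."""
        if j - i <= self.min_loop:
            return False
        return self.max_pair_span is None or j - i <= self.max_pair_span

    # ---- numeric views used by the kernels -------------------------------

    def intra_pair_matrix(self) -> np.ndarray:
        """5x5 matrix of intramolecular pair energies; +inf = disallowed."""
        m = np.full((5, 5), np.inf)
        for pair, e in self.pair_energies.items():
            m[BASE_INDEX[pair[0]], BASE_INDEX[pair[1]]] = e
        return m

    def duplex_pair_index(self) -> np.ndarray:
        """5x5 matrix mapping (query base, target base) -> duplex pair type
        index in :data:`PAIR_TYPES`, or -1 if the bases cannot pair."""
        m = np.full((5, 5), -1, dtype=np.int8)
        for pair, idx in PAIR_TYPE_INDEX.items():
            m[BASE_INDEX[pair[0]], BASE_INDEX[pair[1]]] = idx
        return m

    def stack_matrix(self) -> np.ndarray:
        """6x6 matrix of stacking energies indexed by duplex pair types."""
        m = np.full((len(PAIR_TYPES), len(PAIR_TYPES)), np.inf)
        for (p1, p2), e in self.stack_energies.items():
            m[PAIR_TYPE_INDEX[p1], PAIR_TYPE_INDEX[p2]] = e
        return m

    def intra_stack_matrix(self) -> np.ndarray:
        """6x6 intramolecular stacking energies (0 where unspecified)."""
        m = np.zeros((len(PAIR_TYPES), len(PAIR_TYPES)))
        for (p1, p2), e in self.intra_stack_energies.items():
            m[PAIR_TYPE_INDEX[p1], PAIR_TYPE_INDEX[p2]] = e
        return m

    def intra_stack(self, p1: str, p2: str) -> float:
        """Stacking energy of pair p1 = (x_i, x_j) on p2 = (x_i+1, x_j-1)."""
        return self.intra_stack_energies.get((p1, p2), 0.0)


def default_model() -> EnergyModel:
    """The package's default parameterization (see docs/methods.md)."""
    return EnergyModel()


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested (pseudoknot-free) set of intramolecular pairs (i, j), i < j."""

    pairs: FrozenSet[Tuple[int, int]]

    @staticmethod
    def empty() -> "SecondaryStructure":
        return SecondaryStructure(frozenset())

    def validate(self, seq: str, model: EnergyModel) -> None:
        used: Set[int] = set()
        plist = sorted(self.pairs)
        for i, j in plist:
            if not (0 <= i < j < len(seq)):
                raise ValueError(f"pair {(i, j)} out of range")
            if not model.pair_allowed(i, j):
                raise ValueError(f"pair {(i, j)} violates the span constraints")
            if seq[i] + seq[j] not in model.pair_energies:
                raise ValueError(f"pair {(i, j)} has disallowed type {seq[i]}{seq[j]}")
            if i in used or j in used:
                raise ValueError(f"position reused by pair {(i, j)}")
            used.add(i)
            used.add(j)
        for a in range(len(plist)):
            for b in range(a + 1, len(plist)):
                (i, j), (k, l) = plist[a], plist[b]
                if i < k < j < l:
                    raise ValueError(f"crossing pairs {(i, j)} and {(k, l)}")


def structure_energy(seq: str, structure: SecondaryStructure, model: EnergyModel) -> float:
    """Free energy of ``structure`` under the cooperative helix model.

    Each pair contributes its pair energy; a pair stacked on the pair
    directly inside it ((i+1, j-1) also present) adds the stacking term,
    otherwise it is the innermost pair of its helix and pays ``helix_init``.
    The empty structure has energy 0.
    """
    structure.validate(seq, model)
    total = 0.0
    for i, j in structure.pairs:
        total += model.pair_energies[seq[i] + seq[j]]
        if (i + 1, j - 1) in structure.pairs:
            total += model.intra_stack(seq[i] + seq[j], seq[i + 1] + seq[j - 1])
        else:
            total += model.helix_init
    return total


def enumerate_structures(
    seq: str,
    model: EnergyModel,
    constraint: Optional[Region] = None,
) -> List[SecondaryStructure]:
    """Exhaustively enumerate all nested structures of a short sequence.

    Intended as the brute-force oracle behind the partition-function and
    accessibility dynamic programs; refuses sequences longer than
    ``model.oracle_limit``.  ``constraint`` forces a region to stay unpaired.
    The empty structure is always included.
    """
    n = len(seq)
    if n > model.oracle_limit:
        raise ValueError(
            f"sequence length {n} exceeds oracle limit {model.oracle_limit}; "
            "the enumeration oracle is for tests only"
        )
    blocked = np.zeros(n, dtype=bool)
    if constraint is not None:
        if constraint.end > n:
            raise ValueError("constraint outside sequence")
        blocked[constraint.start : constraint.end] = True

    memo: Dict[Tuple[int, int], List[FrozenSet[Tuple[int, int]]]] = {}

    def rec(i: int, j: int) -> List[FrozenSet[Tuple[int, int]]]:
        # all nested pair sets on the half-open interval [i, j)
        if j - i <= model.min_loop + 1:
            return [frozenset()]
        key = (i, j)
        if key in memo:
            return memo[key]
        out = list(rec(i + 1, j))  # position i unpaired
        if not blocked[i]:
            for k in range(i + model.min_loop + 1, j):
                if (
                    blocked[k]
                    or not model.pair_allowed(i, k)
                    or seq[i] + seq[k] not in model.pair_energies
                ):
                    continue
                for inner in rec(i + 1, k):
                    for right in rec(k + 1, j):
                        out.append(inner | right | {(i, k)})
        memo[key] = out
        return out

    structures = rec(0, n)
    assert len(structures) == len(set(structures)), "duplicate structures"
    return [SecondaryStructure(s) for s in structures]


def boltzmann_sum(seq: str, model: EnergyModel, constraint: Optional[Region] = None) -> float:
    """Partition function by exhaustive enumeration (oracle; short seqs only)."""
    rt = model.rt
    return float(
        sum(
            math.exp(-structure_energy(seq, s, model) / rt)
            for s in enumerate_structures(seq, model, constraint)
        )
    )
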