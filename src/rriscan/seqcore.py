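"""Sequence model, FASTA I/O and coordinate conventions.

All coordinates in this package are 0-based, half-open.  Sequences are
single-stranded sense transcripts over the RNA alphabet {A, C, G, U, N};
DNA input (T/t) is normalized to RNA on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Sequence, Union

import numpy as np

RNA_ALPHABET = frozenset("ACGUN")
_INPUT_ALPHABET = frozenset("ACGTUNacgtun")

#: Watson-Crick complement; N stays N (never counted as a partner downstream).
COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C", "N": "N"}

_COMPLEMENT_TABLE = str.maketrans(COMPLEMENT)

#: integer encoding shared with the numeric kernels
BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; message carries the line number."""


def encode(residues: str) -> np.ndarray:
    """Integer encoding of an RNA string (A=0, C=1, G=2, U=3, N=4)."""
    return np.array([BASE_INDEX[c] for c in residues], dtype=np.int8)


def normalize_residues(raw: str) -> str:
    """Uppercase and convert T->U.  Raises ValueError on illegal residues."""
    seq = raw.upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(f"illegal residue(s): {sorted(bad)}")
    return seq


@dataclass
class RnaSequence:
    """An identified RNA string with a per-position soft-mask flag.

    ``mask[i]`` is True when position ``i`` is excluded from seed matching
    (e.g. inside a tandem repeat).  Masked positions keep their coordinates
    and may still appear inside energy-evaluation windows.
    """

    id: str
    residues: str
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        self.residues = normalize_residues(self.residues)
        if self.mask is None:
            self.mask = np.zeros(len(self.residues), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (len(self.residues),):
                raise ValueError("mask length must equal sequence length")

    def __len__(self) -> int:
        return len(self.residues)

    def codes(self) -> np.ndarray:
        """Integer encoding of the residues (A=0, C=1, G=2, U=3, N=4)."""
        return encode(self.residues)


@dataclass(frozen=True, order=True)
class Region:
    """Half-open interval [start, end) on the sequence named ``seq_id``."""

    seq_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid region [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        return self.seq_id == other.seq_id and (
            self.start < other.end and other.start < self.end
        )


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement (A<->U, C<->G, N<->N)."""
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(f"illegal residue(s): {sorted(bad)}")
    return seq.translate(_COMPLEMENT_TABLE)[::-1]


def read_fasta(path: Union[str, Path]) -> List[RnaSequence]:
    """Read a multi-FASTA file into a list of :class:`RnaSequence`.

    Ids are the first whitespace-delimited token of the header.  T/t is
    normalized to U, lowercase is uppercased, and the mask starts all-False.
    Malformed headers, illegal characters and duplicate ids raise
    :class:`FastaParseError` naming the offending line.
    """
    path = Path(path)
    records: List[RnaSequence] = []
    seen = set()
    header = None
    chunks: List[str] = []
    header_line = 0

    def flush() -> None:
        if header is None:
            return
        if header in seen:
            raise FastaParseError(
                f"{path}:{header_line}: duplicate sequence id {header!r}"
            )
        seen.add(header)
        records.append(RnaSequence(id=header, residues="".join(chunks)))

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                token = line[1:].split()
                if not token:
                    raise FastaParseError(f"{path}:{lineno}: empty FASTA header")
                header = token[0]
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}:{lineno}: sequence data before first header"
                    )
                bad = set(line) - _INPUT_ALPHABET
                if bad:
                    raise FastaParseError(
                        f"{path}:{lineno}: illegal character(s) {sorted(bad)}"
                    )
                chunks.append(line)
        flush()
    return records


def write_fasta(seqs: Iterable[RnaSequence], path: Union[str, Path], width: int = 70) -> None:
    """Write sequences as multi-FASTA (wrap at ``width`` columns)."""
    with open(path, "w") as fh:
        for seq in seqs:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


def merge_intervals(intervals: Sequence[tuple]) -> List[tuple]:
    """Union of half-open intervals, returned sorted and disjoint."""
    out: List[tuple] = []
    for start, end in sorted(intervals):
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def allowed_positions(length: int, regions: Sequence[Region] = None, mask: np.ndarray = None) -> np.ndarray:
    """Boolean vector of positions inside ``regions`` and not masked.

    ``regions=None`` means the whole sequence is allowed.
    """
    if regions is None:
        allowed = np.ones(length, dtype=bool)
    else:
        allowed = np.zeros(length, dtype=bool)
        for r in regions:
            allowed[r.start : r.end] = True
    if mask is not None:
        allowed &= ~np.asarray(mask, dtype=bool)
    return allowed
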