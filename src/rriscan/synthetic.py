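"""Synthetic benchmark generator with planted interactions.

Creates a query set and a target set of i.i.d.-background RNAs in which each
query has exactly one true target: that target carries the exact reverse
complement of a random query subsequence (the *plant*), embedded in a
pairing-poor A/C flank so the site is accessible.  Optionally, a fraction of
the remaining decoy targets carry the *same* complement placed inside a
designed hairpin stem (the plant is immediately followed by a short loop and
its own reverse complement), so the sequence signal is present but the site
is intramolecularly occluded — the negative class that isolates exactly what
accessibility filtering claims to contribute.  All remaining targets are
pure background.

Everything is reproducible from ``rng_seed``; the truth table lists exactly
the (query, true-target) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Tuple, Union

import numpy as np

from .evaluate import TruthTable
from .seqcore import RnaSequence, reverse_complement, write_fasta

#: unstructured flank around accessible plants: poly-A cannot pair with
#: itself, and at the default maximum pair span a flank this long isolates
#: the site from everything except the flank
ACCESSIBLE_FLANK = 60
#: spacer around the occluding hairpin cassette
OCCLUDED_SPACER = 5
#: extra stem on each side of an occluded plant, so the buried site does not
#: touch accessible sequence and seeds cannot escape the filter by extending
#: a base or two past the plant
OCCLUDED_STEM_EXT = 6
#: hairpin loop closing the occluding stem (must exceed the minimum loop size)
HAIRPIN_LOOP = "AACA"


@dataclass(frozen=True)
class BenchmarkSpec:
    """Geometry and composition of the synthetic benchmark."""

    n_queries: int = 20
    n_targets: int = 100
    q_len: int = 200
    t_len: int = 300
    site_len: int = 12
    fraction_occluded: float = 0.0
    gc_content: float = 0.5
    rng_seed: int = 42

    def __post_init__(self) -> None:
        if self.site_len > min(self.q_len, self.t_len):
            raise ValueError("site_len must fit in both query and target")
        if not (0.0 <= self.fraction_occluded <= 1.0):
            raise ValueError("fraction_occluded must be in [0, 1]")
        if not (0.0 < self.gc_content < 1.0):
            raise ValueError("gc_content must be in (0, 1)")
        if self.n_targets < self.n_queries:
            raise ValueError("need at least one target per query")


@dataclass(frozen=True)
class PlantedSite:
    """Coordinates of a planted complement on a target ([start, end))."""

    query_id: str
    target_id: str
    start: int
    end: int
    kind: str  # "accessible" | "occluded"


@dataclass
class Benchmark:
    queries: List[RnaSequence]
    targets: List[RnaSequence]
    truth: TruthTable
    sites: List[PlantedSite]
    query_sites: List[Tuple[str, int, int]] = field(default_factory=list)


def _random_rna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(np.array(list("ACGU")), size=length, p=p))


def _unstructured(rng: np.random.Generator, length: int) -> str:
    """Poly-A stretch: cannot pair with itself and offers the planted site
    only weak, helix-initiation-dominated A-U contacts."""
    return "A" * length


def generate_benchmark(spec: BenchmarkSpec) -> Benchmark:
    """Generate (queries, targets, truth, planted-site coordinates)."""
    rng = np.random.default_rng(spec.rng_seed)
    width = max(3, len(str(max(spec.n_queries, spec.n_targets))))

    queries: List[RnaSequence] = []
    plants: List[str] = []
    query_sites: List[Tuple[str, int, int]] = []
    for i in range(spec.n_queries):
        qid = f"Q{i + 1:0{width}d}"
        residues = list(_random_rna(rng, spec.q_len, spec.gc_content))
        # site selection: prefer C/G end residues (a complement planted in a
        # poly-A flank must not extend the flank's A-run, or soft-masking
        # erodes the seed) and at least the background GC fraction (controls
        # the planted duplex strength, so the effect size is composition-
        # independent)
        site_start = int(rng.integers(0, spec.q_len - spec.site_len + 1))
        for _ in range(100):
            site_end = site_start + spec.site_len
            site_res = residues[site_start:site_end]
            gc = sum(c in "CG" for c in site_res)
            if (
                site_res[0] in "CG"
                and site_res[-1] in "CG"
                and gc * 2 >= spec.site_len
            ):
                break
            site_start = int(rng.integers(0, spec.q_len - spec.site_len + 1))
        site_end = site_start + spec.site_len
        # the interacting site is accessible on the query too: unstructured
        # flanks keep it from being buried in the query's own structure, so
        # target-side occlusion is the only accessibility contrast
        fl = min(ACCESSIBLE_FLANK, site_start)
        fr = min(ACCESSIBLE_FLANK, spec.q_len - site_end)
        residues[site_start - fl : site_start] = _unstructured(rng, fl)
        residues[site_end : site_end + fr] = _unstructured(rng, fr)
        site = "".join(residues[site_start:site_end])
        queries.append(RnaSequence(id=qid, residues="".join(residues)))
        plants.append(reverse_complement(site))
        query_sites.append((qid, site_start, site_end))

    n_decoys = spec.n_targets - spec.n_queries
    n_occluded = int(round(spec.fraction_occluded * n_decoys))

    targets: List[RnaSequence] = []
    sites: List[PlantedSite] = []
    truth_pairs = []
    for j in range(spec.n_targets):
        tid = f"T{j + 1:0{width}d}"
        background = list(_random_rna(rng, spec.t_len, spec.gc_content))
        if j < spec.n_queries:
            # true target: accessible plant in an unstructured flank
            plant = plants[j]
            flank = min(ACCESSIBLE_FLANK, (spec.t_len - spec.site_len) // 2)
            cassette = (
                _unstructured(rng, flank) + plant + _unstructured(rng, flank)
            )
            pos = int(rng.integers(0, spec.t_len - len(cassette) + 1))
            background[pos : pos + len(cassette)] = cassette
            start = pos + flank
            sites.append(
                PlantedSite(queries[j].id, tid, start, start + spec.site_len, "accessible")
            )
            truth_pairs.append((queries[j].id, tid))
        elif j - spec.n_queries < n_occluded:
            # occluded decoy: same complement, but inside a hairpin stem
            qi = (j - spec.n_queries) % spec.n_queries
            plant = plants[qi]
            arm = (
                _random_rna(rng, OCCLUDED_STEM_EXT, spec.gc_content)
                + plant
                + _random_rna(rng, OCCLUDED_STEM_EXT, spec.gc_content)
            )
            cassette = (
                _unstructured(rng, OCCLUDED_SPACER)
                + arm
                + HAIRPIN_LOOP
                + reverse_complement(arm)
                + _unstructured(rng, OCCLUDED_SPACER)
            )
            if len(cassette) > spec.t_len:
                raise ValueError("target too short for the occluded cassette")
            pos = int(rng.integers(0, spec.t_len - len(cassette) + 1))
            background[pos : pos + len(cassette)] = cassette
            start = pos + OCCLUDED_SPACER + OCCLUDED_STEM_EXT
            sites.append(
                PlantedSite(queries[qi].id, tid, start, start + spec.site_len, "occluded")
            )
        targets.append(RnaSequence(id=tid, residues="".join(background)))

    return Benchmark(
        queries=queries,
        targets=targets,
        truth=TruthTable.from_pairs(truth_pairs),
        sites=sites,
        query_sites=query_sites,
    )


def write_benchmark(bench: Benchmark, outdir: Union[str, Path]) -> None:
    """Write query/target FASTA plus truth and planted-site TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(bench.queries, outdir / "queries.fasta")
    write_fasta(bench.targets, outdir / "targets.fasta")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("# query_id\ttarget_id\n")
        for q, t in sorted(bench.truth.pairs):
            fh.write(f"{q}\t{t}\n")
    with open(outdir / "planted_sites.tsv", "w") as fh:
        fh.write("# query_id\ttarget_id\tstart\tend\tkind\n")
        for s in bench.sites:
            fh.write(f"{s.query_id}\t{s.target_id}\t{s.start}\t{s.end}\t{s.kind}\n")
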