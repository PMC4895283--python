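import numpy as np
import pytest

from oracles import maximal_segments_bruteforce, seed_scan_bruteforce
from rriscan.seedfind import SeedMatch, find_seeds, seed_score
from rriscan.segments import has_segment_above, maximal_segments
from rriscan.seqcore import Region, RnaSequence, reverse_complement


def random_seq(rng, n):
    return RnaSequence(f"s{rng.integers(1 << 30)}", "".join(rng.choice(list("ACGU"), n)))


class TestMaximalSegments:
    def test_single_perfect_run(self):
        assert maximal_segments([1.0] * 8, 8.0) == [(0, 8, 8.0)]
        assert maximal_segments([1.0] * 8, 9.0) == []

    def test_bridging_beats_splitting(self):
        # joint segment (sum 9) absorbs the -1 column
        scores = [1.0] * 5 + [-1.0] + [1.0] * 5
        assert maximal_segments(scores, 4.0) == [(0, 11, 9.0)]

    def test_matches_bruteforce_on_random_scores(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 60))
            scores = list(rng.choice([1.0, -1.0], size=n))
            for thresh in (1.0, 3.0, 5.0):
                assert maximal_segments(scores, thresh) == maximal_segments_bruteforce(
                    scores, thresh
                )

    def test_segments_never_end_nonpositive(self, rng):
        scores = list(rng.choice([1.0, -1.0], size=200))
        for a, b, _ in maximal_segments(scores, 2.0):
            assert scores[a] > 0 and scores[b - 1] > 0

    def test_has_segment_above_agrees(self, rng):
        for _ in range(100):
            scores = rng.choice([1.0, -1.0], size=int(rng.integers(1, 40)))
            found = bool(maximal_segments(list(scores), 3.0))
            assert has_segment_above(scores, 3.0) == found


class TestFindSeeds:
    def test_perfect_complement(self):
        q = RnaSequence("q", "GGGGGGGG")
        t = RnaSequence("t", "CCCCCCCC")
        seeds = find_seeds(q, t, 8)
        assert len(seeds) == 1
        s = seeds[0]
        assert (s.q_start, s.q_end, s.t_start, s.t_end, s.score) == (0, 8, 0, 8, 8)
        assert find_seeds(q, t, 9) == []

    def test_gu_scores_minus_one(self):
        # G aligned against U is not Watson-Crick here: no seed at threshold 1
        q = RnaSequence("q", "GGGG")
        t = RnaSequence("t", "GGGG")  # reverse complement alignment gives G:G
        assert find_seeds(q, t, 1) == []
        u = RnaSequence("u", "UUUU")  # G:U wobble columns score -1
        assert find_seeds(q, u, 1) == []

    def test_planted_site_found_at_exact_coordinates(self, rng):
        q = random_seq(rng, 60)
        site = q.residues[20:32]
        t_res = "".join(rng.choice(list("AC"), 20)) + reverse_complement(site) + "".join(
            rng.choice(list("AC"), 20)
        )
        t = RnaSequence("t", t_res)
        seeds = find_seeds(q, t, 8)
        assert any(
            s.q_start <= 20 and s.q_end >= 32 and s.t_start <= 20 + 12 and s.score >= 12
            for s in seeds
        )

    def test_matches_bruteforce_scan(self, rng):
        for s_thresh in (3, 4, 6):
            for _ in range(15):
                q = random_seq(rng, int(rng.integers(20, 61)))
                t = random_seq(rng, int(rng.integers(20, 61)))
                got = sorted(
                    (s.q_start, s.q_end, s.t_start, s.t_end, s.score)
                    for s in find_seeds(q, t, s_thresh)
                )
                assert got == seed_scan_bruteforce(q, t, s_thresh)

    def test_symmetry_under_role_swap(self, rng):
        for _ in range(25):
            a = random_seq(rng, 50)
            b = random_seq(rng, 50)
            ab = {(s.q_start, s.q_end, s.t_start, s.t_end, s.score) for s in find_seeds(a, b, 4)}
            ba = {(s.t_start, s.t_end, s.q_start, s.q_end, s.score) for s in find_seeds(b, a, 4)}
            assert ab == ba

    def test_score_threshold_monotonicity(self, rng):
        q, t = random_seq(rng, 80), random_seq(rng, 80)
        counts = [len(find_seeds(q, t, s)) for s in (3, 4, 5, 6, 8)]
        assert counts == sorted(counts, reverse=True)

    def test_region_restriction_never_adds_seeds(self, rng):
        q, t = random_seq(rng, 80), random_seq(rng, 80)
        full = find_seeds(q, t, 4)
        sub = find_seeds(
            q, t, 4,
            q_regions=[Region(q.id, 0, 40)],
            t_regions=[Region(t.id, 10, 70)],
        )
        assert set(map(str, sub)) <= set(map(str, full))
        for s in sub:  # footprint intersects the allowed regions
            assert s.q_start < 40 and s.t_start < 70 and s.t_end > 10

    def test_reported_scores_self_consistent(self, rng):
        q, t = random_seq(rng, 70), random_seq(rng, 70)
        for s in find_seeds(q, t, 4):
            assert seed_score(q, t, s) == s.score
            assert s.score >= 4 and s.length >= 4

    def test_masked_positions_excluded(self, rng):
        q = RnaSequence("q", "GGGGGGGG", mask=np.array([False] * 8))
        t = RnaSequence("t", "CCCCCCCC", mask=np.array([True] * 8))
        assert find_seeds(q, t, 4) == []

    def test_empty_inputs(self):
        q = RnaSequence("q", "GGGG")
        assert find_seeds(q, RnaSequence("t", "AAAA"), 2) == []

    def test_gapless_invariant_enforced(self):
        with pytest.raises(ValueError):
            SeedMatch("q", "t", 0, 5, 0, 4, 3)
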