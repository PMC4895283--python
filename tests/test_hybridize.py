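import numpy as np
import pytest

from oracles import duplex_enumeration_min_eint
from rriscan.accessibility import AccessibilityCalculator
from rriscan.hybridize import (
    LocalInteraction,
    deduplicate_interactions,
    extend_window,
    min_interaction_energy,
)
from rriscan.seedfind import SeedMatch
from rriscan.seqcore import Region, RnaSequence, reverse_complement


def random_seq(rng, n, alphabet="ACGU"):
    return RnaSequence(f"s{rng.integers(1 << 30)}", "".join(rng.choice(list(alphabet), n)))


def interaction(q, t, qw, tw, model):
    cq = AccessibilityCalculator(q, model)
    ct = AccessibilityCalculator(t, model)
    return min_interaction_energy(q, t, qw, tw, model, cq, ct)


class TestExtendWindow:
    @pytest.mark.parametrize(
        "q_start, q_end, w, expected",
        [
            (10, 18, 20, (0, 38)),   # left clip
            (50, 58, 20, (30, 78)),
            (50, 58, 0, (50, 58)),   # w=0 keeps the footprint
            (90, 98, 20, (70, 100)),  # right clip
        ],
    )
    def test_clipping(self, q_start, q_end, w, expected):
        seed = SeedMatch("q", "t", q_start, q_end, 0, q_end - q_start, 8)
        q_win, t_win = extend_window(seed, w, 100, 100)
        assert (q_win.start, q_win.end) == expected
        assert t_win.start == max(0, seed.t_start - w)

    def test_negative_w_rejected(self):
        seed = SeedMatch("q", "t", 0, 8, 0, 8, 8)
        with pytest.raises(ValueError):
            extend_window(seed, -1, 100, 100)


class TestMinInteractionEnergy:
    def test_unpairable_windows_give_none(self, model):
        q = RnaSequence("q", "AAAA")
        t = RnaSequence("t", "AAAA")
        assert interaction(q, t, Region("q", 0, 4), Region("t", 0, 4), model) is None

    def test_perfect_duplex_matches_hand_summation(self, model):
        # G-only 8-mer complement in A-flanks: neither molecule can form any
        # intramolecular pair and the duplex is confined to the site, so
        # E_int = E_hybrid = init + 7 stacks exactly
        site = "GGGGGGGG"
        q = RnaSequence("q", "A" * 10 + site + "A" * 10)
        t = RnaSequence("t", "A" * 10 + reverse_complement(site) + "A" * 10)
        inter = interaction(q, t, Region("q", 0, 28), Region("t", 0, 28), model)
        assert inter is not None
        partner = reverse_complement(site)[::-1]
        stacks = sum(
            model.stack_energies[
                (site[k] + partner[k], site[k + 1] + partner[k + 1])
            ]
            for k in range(7)
        )
        assert inter.e_hybrid == pytest.approx(model.duplex_init + stacks)
        assert inter.ed_query == pytest.approx(0.0, abs=1e-12)
        assert inter.ed_target == pytest.approx(0.0, abs=1e-12)
        assert inter.e_int == pytest.approx(inter.e_hybrid)
        assert len(inter.hybrid_pairs) == 8

    def test_matches_exhaustive_enumeration(self, model, rng):
        for _ in range(25):
            lq = int(rng.integers(4, 11))
            lt = int(rng.integers(4, 11))
            q = random_seq(rng, int(rng.integers(lq, 26)))
            t = random_seq(rng, int(rng.integers(lt, 26)))
            q0 = int(rng.integers(0, len(q) - lq + 1))
            t0 = int(rng.integers(0, len(t) - lt + 1))
            qw, tw = Region(q.id, q0, q0 + lq), Region(t.id, t0, t0 + lt)
            cq, ct = AccessibilityCalculator(q, model), AccessibilityCalculator(t, model)
            got = min_interaction_energy(q, t, qw, tw, model, cq, ct)
            expected = duplex_enumeration_min_eint(q, t, qw, tw, model, cq, ct)
            if expected is None:
                assert got is None
            else:
                assert got is not None
                assert got.e_int == pytest.approx(expected, abs=1e-9)

    def test_invariants_of_returned_interaction(self, model, rng):
        checked = 0
        while checked < 10:
            q = random_seq(rng, 40)
            t = random_seq(rng, 40)
            inter = interaction(q, t, Region(q.id, 0, 40), Region(t.id, 0, 40), model)
            if inter is None:
                continue
            checked += 1
            assert inter.e_int == pytest.approx(
                inter.e_hybrid + inter.ed_query + inter.ed_target, abs=1e-9
            )
            assert inter.ed_query >= 0 and inter.ed_target >= 0
            assert inter.e_int < 0
            qs = [a for a, _ in inter.hybrid_pairs]
            ts = [b for _, b in inter.hybrid_pairs]
            assert qs == sorted(qs) and len(set(qs)) == len(qs)
            assert ts == sorted(ts, reverse=True) and len(set(ts)) == len(ts)
            from rriscan.energy import PAIR_TYPES

            for a, b in inter.hybrid_pairs:
                assert q.residues[a] + t.residues[b] in PAIR_TYPES
            db = inter.dot_bracket()
            assert db.count("(") == db.count(")") == len(inter.hybrid_pairs)

    def test_role_swap_symmetry(self, model, rng):
        for _ in range(10):
            q = random_seq(rng, 30)
            t = random_seq(rng, 30)
            cq, ct = AccessibilityCalculator(q, model), AccessibilityCalculator(t, model)
            ab = min_interaction_energy(
                q, t, Region(q.id, 0, 30), Region(t.id, 0, 30), model, cq, ct
            )
            ba = min_interaction_energy(
                t, q, Region(t.id, 0, 30), Region(q.id, 0, 30), model, ct, cq
            )
            if ab is None:
                assert ba is None
            else:
                assert ba is not None
                assert ab.e_int == pytest.approx(ba.e_int, abs=1e-9)
                assert {(a, b) for a, b in ab.hybrid_pairs} == {
                    (b, a) for a, b in ba.hybrid_pairs
                }

    def test_widening_w_never_raises_optimum(self, model, rng):
        q = random_seq(rng, 80)
        t = random_seq(rng, 80)
        seed = SeedMatch(q.id, t.id, 30, 38, 30, 38, 8)
        cq, ct = AccessibilityCalculator(q, model), AccessibilityCalculator(t, model)
        prev = None
        for w in (0, 5, 10, 20, 40):
            qw, tw = extend_window(seed, w, len(q), len(t))
            inter = min_interaction_energy(q, t, qw, tw, model, cq, ct)
            val = np.inf if inter is None else inter.e_int
            if prev is not None:
                assert val <= prev + 1e-9
            prev = val

    def test_accessibility_penalty_vanishes_without_structure(self, model):
        # poly-A and poly-U parents admit no intramolecular pairs at all
        q = RnaSequence("q", "A" * 24)
        t = RnaSequence("t", "U" * 24)
        inter = interaction(q, t, Region("q", 0, 24), Region("t", 0, 24), model)
        assert inter is not None
        assert inter.ed_query == pytest.approx(0.0, abs=1e-12)
        assert inter.ed_target == pytest.approx(0.0, abs=1e-12)


def make_interaction(e_int, q0, q1, t0, t1):
    return LocalInteraction(
        query_id="q",
        target_id="t",
        q_site=Region("q", q0, q1),
        t_site=Region("t", t0, t1),
        hybrid_pairs=((q0, t1 - 1),),
        e_hybrid=e_int,
        ed_query=0.0,
        ed_target=0.0,
        e_int=e_int,
    )


class TestDeduplicate:
    def test_identical_interactions_collapse(self):
        a = make_interaction(-10, 0, 8, 0, 8)
        b = make_interaction(-10, 0, 8, 0, 8)
        assert deduplicate_interactions([a, b]) == [a]

    def test_disjoint_sites_all_kept(self):
        a = make_interaction(-10, 0, 8, 0, 8)
        b = make_interaction(-5, 20, 28, 20, 28)
        assert deduplicate_interactions([b, a]) == [a, b]  # sorted by e_int

    def test_mutually_overlapping_keep_best(self):
        a = make_interaction(-10, 0, 8, 0, 8)
        b = make_interaction(-8, 4, 12, 4, 12)
        c = make_interaction(-5, 2, 10, 2, 10)
        assert deduplicate_interactions([c, b, a]) == [a]

    def test_overlap_required_on_both_molecules(self):
        a = make_interaction(-10, 0, 8, 0, 8)
        b = make_interaction(-8, 0, 8, 50, 58)  # same query site, distant target site
        assert deduplicate_interactions([a, b]) == [a, b]
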