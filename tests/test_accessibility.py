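import math

import numpy as np
import pytest

from oracles import accessibility_enumeration, boltzmann_sum_enumeration
from rriscan.accessibility import (
    AccessibilityCalculator,
    AccessibilityProfile,
    accessibility_profile,
    accessible_regions,
    partition_function,
)
from rriscan.seqcore import Region


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


class TestPartitionFunction:
    def test_unpairable_sequence_is_one(self, model):
        assert partition_function("AAAA", model) == pytest.approx(1.0)

    def test_gggccc_closed_form(self, reference_model):
        # GGGCCC admits exactly the single pairs (0,4), (0,5), (1,5)
        expected = 1.0 + 3.0 * math.exp(2.0 / reference_model.rt)
        assert partition_function("GGGCCC", reference_model) == pytest.approx(
            expected, rel=1e-12
        )

    def test_z_at_least_one(self, model, rng):
        for _ in range(10):
            seq = random_seq(rng, int(rng.integers(1, 40)))
            assert partition_function(seq, model) >= 1.0

    def test_matches_enumeration_including_constrained(self, model, rng):
        for _ in range(25):
            n = int(rng.integers(5, 16))
            seq = random_seq(rng, n)
            assert partition_function(seq, model) == pytest.approx(
                boltzmann_sum_enumeration(seq, model), rel=1e-9
            )
            a = int(rng.integers(0, n - 1))
            b = int(rng.integers(a + 1, n + 1))
            region = Region("x", a, b)
            assert partition_function(seq, model, region) == pytest.approx(
                boltzmann_sum_enumeration(seq, model, region), rel=1e-9
            )

    def test_empty_sequence_rejected(self, model):
        with pytest.raises(ValueError):
            partition_function("", model)


class TestProfile:
    def test_unstructured_sequence_all_zero(self, model):
        profile = accessibility_profile("A" * 12, 4, model)
        assert len(profile) == 9
        assert np.allclose(profile.energies, 0.0)

    def test_short_sequence_gives_empty_profile(self, model):
        assert len(accessibility_profile("ACG", 5, model)) == 0

    def test_profile_matches_enumeration(self, model, rng):
        seq = random_seq(rng, 16)
        profile = accessibility_profile(seq, 5, model)
        for i, e in enumerate(profile.energies):
            expected = max(0.0, accessibility_enumeration(seq, i, i + 5, model))
            assert e == pytest.approx(expected, abs=1e-8)

    def test_hairpin_stem_less_accessible_than_loop(self, model):
        calc = AccessibilityCalculator("GGGGAAAACCCC", model)
        assert calc.span_energy(0, 4) > calc.span_energy(4, 8)

    def test_energies_non_negative_and_monotone_nesting(self, model, rng):
        for _ in range(15):
            n = int(rng.integers(10, 36))
            calc = AccessibilityCalculator(random_seq(rng, n), model)
            finite = calc.span_ed[np.isfinite(calc.span_ed)]
            assert (finite >= 0.0).all()
            a = int(rng.integers(0, n - 2))
            b = int(rng.integers(a + 2, n + 1))
            inner_a = int(rng.integers(a, b - 1))
            inner_b = int(rng.integers(inner_a + 1, b + 1))
            assert calc.span_energy(a, b) >= calc.span_energy(inner_a, inner_b) - 1e-9


class TestAccessibleRegions:
    def make_profile(self, energies, s):
        return AccessibilityProfile("x", s, np.asarray(energies, dtype=float))

    def test_infinite_threshold_covers_everything(self):
        profile = self.make_profile([0.5, 3.0, 1.0], 4)
        assert accessible_regions(profile, math.inf) == [Region("x", 0, 6)]

    @pytest.mark.parametrize("t", [0.0, -1.0])
    def test_nonpositive_threshold_rejects_all(self, t):
        profile = self.make_profile([0.0, 0.1, 0.2], 4)
        assert accessible_regions(profile, t) == []

    def test_window_union_merging(self):
        profile = self.make_profile([0.1, 5.0, 0.2, 0.3], 4)
        assert accessible_regions(profile, 1.0) == [Region("x", 0, 7)]

    def test_strict_inequality_at_threshold(self):
        profile = self.make_profile([1.0, 0.99], 3)
        assert accessible_regions(profile, 1.0) == [Region("x", 1, 4)]

    def test_total_length_non_decreasing_in_t(self, model, rng):
        calc = AccessibilityCalculator(random_seq(rng, 40), model)
        profile = calc.profile(6)
        lengths = []
        for t in (0.5, 1.0, 2.0, 4.0, math.inf):
            regions = accessible_regions(profile, t)
            lengths.append(sum(len(r) for r in regions))
        assert lengths == sorted(lengths)

    def test_region_length_at_least_window(self, model, rng):
        calc = AccessibilityCalculator(random_seq(rng, 50), model)
        profile = calc.profile(8)
        for r in accessible_regions(profile, 3.0):
            assert len(r) >= 8
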