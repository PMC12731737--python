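import math

import numpy as np
import pytest

from entroseg import (combined_masi, combined_shannon, combined_tsallis,
                      masi, shannon, split_classes, tsallis)
from conftest import histogram_from_counts
from oracles import bf_shannon


def random_dist(rng, n):
    p = rng.random(n)
    return p / p.sum()


class TestShannon:
    def test_certainty(self):
        assert shannon([1.0]).value == 0.0

    def test_uniform_two(self):
        assert shannon([0.5, 0.5]).value == pytest.approx(math.log(2), abs=1e-12)

    def test_matches_extended_precision_sum(self):
        p = [0.1, 0.2, 0.3, 0.4]
        assert shannon(p).value == pytest.approx(float(bf_shannon(p)), abs=1e-14)

    def test_bad_input(self):
        with pytest.raises(ValueError):
            shannon([0.5, 0.6])
        with pytest.raises(ValueError):
            shannon([-0.1, 1.1])

    @pytest.mark.parametrize("n", [2, 5, 16])
    def test_max_at_uniform(self, rng, n):
        assert shannon(np.full(n, 1 / n)).value == pytest.approx(math.log(n), abs=1e-12)
        for _ in range(20):
            assert shannon(random_dist(rng, n)).value <= math.log(n) + 1e-12


class TestTsallis:
    def test_q2_closed_form(self):
        assert tsallis([0.5, 0.5], 2.0).value == pytest.approx(0.5, abs=1e-12)

    def test_q_half(self):
        exp = (math.sqrt(0.25) + math.sqrt(0.75) - 1) / 0.5
        assert tsallis([0.25, 0.75], 0.5).value == pytest.approx(exp, abs=1e-12)

    @pytest.mark.parametrize("eps", [1e-6, -1e-6])
    def test_near_one_routes_to_shannon(self, eps):
        p = [0.1, 0.2, 0.3, 0.4]
        assert tsallis(p, 1 + eps).value == pytest.approx(shannon(p).value, abs=1e-5)

    def test_pseudo_additivity_products(self, rng):
        """S_q(A x B) = S_q(A) + S_q(B) + (1-q) S_q(A) S_q(B)."""
        for _ in range(100):
            pa = random_dist(rng, rng.integers(2, 6))
            pb = random_dist(rng, rng.integers(2, 6))
            q = rng.uniform(0.1, 2.5)
            if abs(q - 1) < 1e-3:
                continue
            prod = np.outer(pa, pb).ravel()
            sa, sb = tsallis(pa, q).value, tsallis(pb, q).value
            expected = sa + sb + (1 - q) * sa * sb
            assert tsallis(prod, q).value == pytest.approx(expected, abs=1e-10)


class TestMasi:
    @pytest.mark.parametrize("eps", [1e-6, -1e-6])
    def test_near_one_routes_to_shannon(self, eps):
        p = [0.1, 0.2, 0.3, 0.4]
        assert masi(p, 1 + eps).value == pytest.approx(shannon(p).value, abs=1e-5)

    def test_r2_closed_form(self):
        assert masi([0.5, 0.5], 2.0).value == pytest.approx(
            -math.log(1 - math.log(2)), abs=1e-12)

    def test_invalid_outside_domain(self):
        # uniform over 16 levels: S = ln 16 > 1, so 1 - S < 0 at r = 2
        v = masi(np.full(16, 1 / 16), 2.0)
        assert not v.valid and math.isnan(v.value)

    def test_r_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            masi([0.5, 0.5], -0.5)

    def test_validity_monotone_in_r(self, rng):
        """Once invalid at some r > 1, invalid at every larger r."""
        for _ in range(20):
            p = random_dist(rng, 32)
            rs = np.linspace(1.01, 3.0, 40)
            flags = [masi(p, r).valid for r in rs]
            # flags must be non-increasing: True ... True False ... False
            assert all(a or not b for a, b in zip(flags, flags[1:]))


class TestCombinedObjectives:
    def test_both_classes_certain(self):
        h = histogram_from_counts([1, 1])
        s = split_classes(h, 0)
        assert combined_shannon(s) == 0.0
        assert combined_tsallis(s, 0.7) == 0.0
        assert combined_masi(s, 1.3).value == 0.0

    def test_uniform_four_levels(self):
        h = histogram_from_counts([1, 1, 1, 1])
        assert combined_shannon(split_classes(h, 1)) == pytest.approx(
            2 * math.log(2), abs=1e-12)

    def test_shannon_composition(self):
        h = histogram_from_counts([1, 2, 3, 4])
        s = split_classes(h, 1)
        expected = shannon([1 / 3, 2 / 3]).value + shannon([3 / 7, 4 / 7]).value
        assert combined_shannon(s) == pytest.approx(expected, abs=1e-12)

    def test_tsallis_composition(self, rng):
        counts = rng.integers(1, 20, size=8)
        h = histogram_from_counts(counts)
        s = split_classes(h, 3)
        q = 0.8
        sa, sb = tsallis(s.dist_a, q).value, tsallis(s.dist_b, q).value
        assert combined_tsallis(s, q) == pytest.approx(
            sa + sb + (1 - q) * sa * sb, abs=1e-12)

    def test_tsallis_limit_is_shannon(self, rng):
        counts = rng.integers(1, 20, size=8)
        h = histogram_from_counts(counts)
        s = split_classes(h, 3)
        assert combined_tsallis(s, 1 + 1e-6) == pytest.approx(
            combined_shannon(s), abs=1e-5)
        assert combined_masi(s, 1 + 1e-6).value == pytest.approx(
            combined_shannon(s), abs=1e-5)

    def test_masi_invalid_near_uniform(self, rng):
        counts = rng.integers(90, 110, size=256)
        h = histogram_from_counts(counts)
        s = split_classes(h, 128)
        assert not combined_masi(s, 1.7).valid
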