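"""Tests for the triad census, null model, surprise statistic, and energy."""

from itertools import combinations

import numpy as np
import pytest

from genebalance.triads import (
    NullEnsemble,
    TriadCensus,
    count_triads,
    energy,
    shuffle_signs,
    shuffled_networks,
    surprise,
    triangle_list,
)
from .conftest import brute_force_census, brute_force_energy, net_from_weights, random_signed_weights


def _triangle(w_ab, w_bc, w_ca):
    values = np.zeros((3, 3))
    values[0, 1] = values[1, 0] = w_ab
    values[1, 2] = values[2, 1] = w_bc
    values[0, 2] = values[2, 0] = w_ca
    return net_from_weights(values)


class TestCountTriads:
    def test_all_positive_triangle(self):
        census = count_triads(_triangle(0.5, 0.5, 0.5))
        assert census.counts == (0, 0, 0, 1)
        assert (census.balanced, census.unbalanced, census.total) == (1, 0, 1)

    def test_one_negative_edge_is_strongly_unbalanced(self):
        census = count_triads(_triangle(0.5, 0.5, -0.5))
        assert census.counts == (0, 0, 1, 0)
        assert (census.balanced, census.unbalanced) == (0, 1)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_enumeration(self, seed):
        """Census equals the brute-force loop over all C(n,3) triples."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        net = net_from_weights(random_signed_weights(n, rng))
        census = count_triads(net)
        assert census.counts == brute_force_census(net)

    @pytest.mark.parametrize("seed", range(10))
    def test_sign_flip_swaps_type_pairs(self, seed):
        """Negating all signs maps T3 <-> T0 and T2 <-> T1."""
        rng = np.random.default_rng(seed)
        w = random_signed_weights(8, rng)
        c_pos = count_triads(net_from_weights(w))
        c_neg = count_triads(net_from_weights(-w))
        t0, t1, t2, t3 = c_pos.counts
        assert c_neg.counts == (t3, t2, t1, t0)

    def test_no_triangles(self):
        values = np.zeros((4, 4))
        values[0, 1] = values[1, 0] = 0.5
        values[2, 3] = values[3, 2] = -0.5
        census = count_triads(net_from_weights(values))
        assert census.total == 0
        assert np.all(census.fractions == 0.0)


class TestShuffleSigns:
    def test_all_positive_network_null_is_trivial(self):
        rng = np.random.default_rng(0)
        net = net_from_weights(np.abs(random_signed_weights(6, rng, p_edge=1.0)))
        null = shuffle_signs(net, M=5, seed=1)
        assert np.allclose(null.mean_fractions, [0, 0, 0, 1])

    def test_same_seed_reproduces_ensemble(self):
        rng = np.random.default_rng(1)
        net = net_from_weights(random_signed_weights(8, rng))
        a = shuffle_signs(net, M=10, seed=3)
        b = shuffle_signs(net, M=10, seed=3)
        assert [c.counts for c in a.censuses] == [c.counts for c in b.censuses]

    def test_k4_matches_exhaustive_sign_placement_expectation(self):
        """Null fractions on K4 with 3+/3- signs approach the exact average
        over all C(6,3) = 20 equally likely sign placements."""
        edges = list(combinations(range(4), 2))
        exact = np.zeros(4)
        for neg_set in combinations(range(6), 3):
            values = np.zeros((4, 4))
            for e, (i, j) in enumerate(edges):
                w = -0.5 if e in neg_set else 0.5
                values[i, j] = values[j, i] = w
            exact += count_triads(net_from_weights(values)).fractions
        exact /= 20.0

        values = np.zeros((4, 4))
        for e, (i, j) in enumerate(edges):
            w = -0.5 if e < 3 else 0.5
            values[i, j] = values[j, i] = w
        net = net_from_weights(values)
        null = shuffle_signs(net, M=2000, seed=7)
        assert np.allclose(null.mean_fractions, exact, atol=0.03)

    def test_weight_mode_preserves_weight_multiset(self):
        rng = np.random.default_rng(5)
        net = net_from_weights(random_signed_weights(7, rng))
        ii, jj = net.edge_index()
        original = np.sort(net.weights[ii, jj])
        for shuffled in shuffled_networks(net, M=3, seed=9, mode="weights"):
            assert np.allclose(np.sort(shuffled.weights[ii, jj]), original)
            assert np.array_equal(shuffled.unsigned_adjacency, net.unsigned_adjacency)

    def test_signs_only_mode_preserves_magnitudes_in_place(self):
        rng = np.random.default_rng(6)
        net = net_from_weights(random_signed_weights(7, rng))
        ii, jj = net.edge_index()
        for shuffled in shuffled_networks(net, M=3, seed=9, mode="signs-only"):
            assert np.allclose(np.abs(shuffled.weights[ii, jj]), np.abs(net.weights[ii, jj]))


class TestSurprise:
    def test_zero_when_observed_equals_expected(self):
        census = TriadCensus(counts=(25, 25, 25, 25), balanced=50, unbalanced=50, total=100)
        null = NullEnsemble(censuses=(census,), seed=0, mode="signs-only")
        table = surprise(census, null)
        assert np.allclose(table.s, 0.0)

    def test_hand_computed_value(self):
        """Delta=100, |T3|=30, p0(T3)=0.2 -> s = 10/sqrt(16) = 2.5."""
        census = TriadCensus(counts=(20, 30, 20, 30), balanced=60, unbalanced=40, total=100)
        null_census = TriadCensus(counts=(30, 30, 20, 20), balanced=50, unbalanced=50, total=100)
        null = NullEnsemble(censuses=(null_census,), seed=0, mode="signs-only")
        table = surprise(census, null)
        assert table.s[3] == pytest.approx(2.5)
        assert table.s_over_delta[3] == pytest.approx(0.025)

    def test_degenerate_null_fraction_flagged_not_scored(self):
        census = TriadCensus(counts=(0, 0, 0, 4), balanced=4, unbalanced=0, total=4)
        null = NullEnsemble(censuses=(census,), seed=0, mode="signs-only")
        table = surprise(census, null)
        assert table.degenerate[3] and table.degenerate[0]
        assert np.isnan(table.s[3])

    def test_sign_matches_over_underrepresentation(self):
        census = TriadCensus(counts=(10, 40, 10, 40), balanced=80, unbalanced=20, total=100)
        null_census = TriadCensus(counts=(25, 25, 25, 25), balanced=50, unbalanced=50, total=100)
        null = NullEnsemble(censuses=(null_census,), seed=0, mode="signs-only")
        table = surprise(census, null)
        assert np.all(np.sign(table.s) == np.sign(table.p - table.p0))


class TestEnergy:
    def test_single_balanced_triangle(self):
        assert energy(_triangle(0.5, 0.5, 0.5)).network_energy == pytest.approx(-1.0)

    def test_single_unbalanced_triangle(self):
        assert energy(_triangle(0.5, 0.5, -0.5)).network_energy == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        net = net_from_weights(random_signed_weights(5, rng, p_edge=0.9))
        if triangle_list(net).shape[0] == 0:
            pytest.skip("no triangles drawn")
        assert energy(net).network_energy == pytest.approx(brute_force_energy(net), abs=1e-12)

    @pytest.mark.parametrize("scale", [0.1, 0.3, 0.9])
    def test_invariant_under_positive_weight_scaling(self, scale):
        """E is normalized by Delta_w, so uniform rescaling leaves it unchanged."""
        rng = np.random.default_rng(42)
        w = random_signed_weights(6, rng, p_edge=1.0)
        e1 = energy(net_from_weights(w)).network_energy
        e2 = energy(net_from_weights(w * scale)).network_energy
        assert e2 == pytest.approx(e1, abs=1e-12)

    def test_no_triads_raises(self):
        values = np.zeros((3, 3))
        values[0, 1] = values[1, 0] = 0.5
        with pytest.raises(ValueError, match="no triads"):
            energy(net_from_weights(values))

    def test_mean_energy_sign_by_type(self):
        """Balanced triads carry negative energy, unbalanced positive."""
        rng = np.random.default_rng(11)
        net = net_from_weights(random_signed_weights(10, rng, p_edge=0.9))
        res = energy(net)
        for t, sign in ((3, -1), (1, -1), (2, 1), (0, 1)):
            if not np.isnan(res.mean_energy_by_type[t]):
                assert np.sign(res.mean_energy_by_type[t]) == sign
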