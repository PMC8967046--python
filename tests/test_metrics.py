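"""Tests for graph indicators, small-world measures, and spectral comparison."""

import networkx as nx
import numpy as np
import pytest

from genebalance.io import SimilarityMatrix, threshold_network
from genebalance.metrics import (
    basic_indicators,
    clustering_and_path,
    graph_indicators,
    reference_networks,
    small_world_measures,
    spectrum_vs_shuffled,
)
from .conftest import net_from_weights, random_signed_weights


def _net_from_graph(g: nx.Graph, weight: float = 0.5):
    values = nx.to_numpy_array(g) * weight
    return net_from_weights(values)


class TestBasicIndicators:
    def test_regular_graph_has_unit_degree_ratio(self):
        ind = basic_indicators(_net_from_graph(nx.cycle_graph(10)))
        assert ind.degree_ratio == pytest.approx(1.0)
        assert ind.mean_degree == pytest.approx(2.0)

    def test_star_graph_is_disassortative(self):
        ind = basic_indicators(_net_from_graph(nx.star_graph(5)))
        assert ind.assortativity < 0

    def test_modular_graph_has_high_modularity(self):
        g = nx.union(nx.complete_graph(6), nx.complete_graph(6), rename=("a", "b"))
        g.add_edge("a0", "b0")
        ind = basic_indicators(_net_from_graph(nx.convert_node_labels_to_integers(g)))
        assert ind.modularity > 0.3

    def test_edgeless_network_raises(self):
        with pytest.raises(ValueError):
            basic_indicators(net_from_weights(np.zeros((4, 4))))


class TestClusteringAndPath:
    def test_triangle(self):
        c, ell = clustering_and_path(_net_from_graph(nx.complete_graph(3)))
        assert (c, ell) == (1.0, 1.0)

    def test_path_graph(self):
        c, ell = clustering_and_path(_net_from_graph(nx.path_graph(3)))
        assert c == 0.0
        assert ell == pytest.approx(4.0 / 3.0)

    def test_path_length_uses_largest_component(self):
        g = nx.union(nx.path_graph(4), nx.path_graph(2), rename=("a", "b"))
        _, ell = clustering_and_path(_net_from_graph(nx.convert_node_labels_to_integers(g)))
        # distances within the 4-node path: 1,1,1,2,2,3 -> mean 10/6
        assert ell == pytest.approx(10.0 / 6.0)

    def test_random_graph_clustering_near_density(self):
        """For G(n, m), E[C] equals the edge density."""
        rng = np.random.default_rng(0)
        cs = []
        for seed in range(10):
            g = nx.gnm_random_graph(40, 200, seed=seed)
            c, _ = clustering_and_path(_net_from_graph(g))
            cs.append(c)
        density = 200 / (40 * 39 / 2)
        assert np.mean(cs) == pytest.approx(density, abs=0.05)


class TestReferenceNetworks:
    def test_ring_lattice_is_its_own_lattice_reference(self):
        net = _net_from_graph(nx.watts_strogatz_graph(30, 6, 0.0))
        c, ell = clustering_and_path(net)
        _, _, c_latt, l_latt = reference_networks(net, n_realizations=2, seed=0)
        assert c_latt == pytest.approx(c)
        assert l_latt == pytest.approx(ell)

    def test_lattice_clustering_closed_form_k4(self):
        """Ring lattice with k = 4 has C = 3(k-2)/(4(k-1)) = 0.5."""
        net = _net_from_graph(nx.watts_strogatz_graph(20, 4, 0.0))
        _, _, c_latt, _ = reference_networks(net, n_realizations=1, seed=0)
        assert c_latt == pytest.approx(0.5)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        net = net_from_weights(random_signed_weights(15, rng, p_edge=0.4))
        assert reference_networks(net, 3, seed=5) == reference_networks(net, 3, seed=5)

    def test_low_degree_raises(self):
        values = np.zeros((4, 4))
        values[0, 1] = values[1, 0] = 0.5
        with pytest.raises(ValueError, match="mean degree"):
            reference_networks(net_from_weights(values))


class TestSmallWorldMeasures:
    REFS = (0.1, 2.0, 0.6, 4.0)  # C_rand, L_rand, C_latt, L_latt

    def test_perfect_small_world(self):
        sw = small_world_measures(C=0.6, L=2.0, references=self.REFS)
        assert sw["delta_C"] == 0.0
        assert sw["delta_L"] == 0.0
        assert sw["propensity"] == pytest.approx(1.0)

    def test_worst_case_clipped_extremes(self):
        sw = small_world_measures(C=0.1, L=4.0, references=self.REFS)
        assert sw["propensity"] == pytest.approx(0.0)

    def test_random_like_network(self):
        """C = C_rand and L = L_rand forces phi = 1 - sqrt(1/2)."""
        sw = small_world_measures(C=0.1, L=2.0, references=self.REFS)
        assert sw["delta_C"] == 1.0
        assert sw["delta_L"] == 0.0
        assert sw["propensity"] == pytest.approx(1.0 - np.sqrt(0.5))
        assert sw["C_norm"] == pytest.approx(0.0)

    def test_degenerate_references_raise(self):
        with pytest.raises(ValueError, match="degenerate"):
            small_world_measures(0.5, 2.0, (0.3, 2.0, 0.3, 4.0))

    def test_self_reference_sw_is_one(self):
        sw = small_world_measures(C=0.4, L=2.5, references=(0.4, 2.5, 0.9, 5.0))
        assert sw["small_world_index"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_propensity_invariant_under_relabeling(self, seed):
        rng = np.random.default_rng(seed)
        w = random_signed_weights(20, rng, p_edge=0.3)
        perm = rng.permutation(20)
        a = graph_indicators(net_from_weights(w), n_realizations=2, seed=1)
        b = graph_indicators(net_from_weights(w[np.ix_(perm, perm)]), n_realizations=2, seed=1)
        assert b.propensity == pytest.approx(a.propensity, abs=1e-12)
        assert b.clustering == pytest.approx(a.clustering, abs=1e-12)


class TestSpectrum:
    def _sim(self, values):
        return SimilarityMatrix(values=values, gene_ids=tuple(f"g{i}" for i in range(values.shape[0])))

    def test_eigenvalue_sum_is_zero_trace(self):
        rng = np.random.default_rng(0)
        spec = spectrum_vs_shuffled(self._sim(random_signed_weights(20, rng)), n_shuffles=3, seed=1)
        assert spec.eigenvalues.sum() == pytest.approx(0.0, abs=1e-8)

    def test_squared_eigenvalues_match_frobenius_norm(self):
        rng = np.random.default_rng(1)
        values = random_signed_weights(20, rng)
        spec = spectrum_vs_shuffled(self._sim(values), n_shuffles=3, seed=1)
        assert np.sum(spec.eigenvalues**2) == pytest.approx(np.sum(values**2), abs=1e-8)

    def test_unstructured_matrix_has_no_clear_outliers(self):
        rng = np.random.default_rng(2)
        values = random_signed_weights(40, rng, p_edge=1.0) * 0.3
        spec = spectrum_vs_shuffled(self._sim(values), n_shuffles=10, seed=3)
        assert spec.n_outliers <= 1

    def test_planted_blocks_produce_outliers_above_bulk(self):
        """Five anti-correlated modules push >= 3 eigenvalues above the bulk."""
        from genebalance.synthetic import ProfileModel, generate_profiles, profiles_to_similarity

        model = ProfileModel(n_genes=100, n_modules=5, profile_length=400,
                             within_module_corr=0.5, between_module_corr=-0.125, seed=5)
        sim = profiles_to_similarity(generate_profiles(model))
        spec = spectrum_vs_shuffled(sim, n_shuffles=10, seed=0)
        assert spec.n_above_bulk >= 3
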