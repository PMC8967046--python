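"""Standard graph indicators, small-world measures, and spectral comparison.

Six indicators characterise the thresholded (unsigned, unweighted) network:
mean degree k, the degree-fluctuation ratio <k^2>/<k>^2, modularity Q,
degree assortativity r, mean local clustering C and mean shortest path
length L. C and L depend strongly on N and k, so they are normalized
against matched random (same N, same edge count) and ring-lattice
references:

    C~ = (C - C_rand)/(C_latt - C_rand),   L~ = (L - L_rand)/(L_latt - L_rand)
    SW = (C/C_rand) / (L/L_rand)
    phi = 1 - sqrt((Delta_C^2 + Delta_L^2)/2)

with Delta_C = (C_latt - C)/(C_latt - C_rand) and
Delta_L = (L - L_rand)/(L_latt - L_rand), each clipped to [0, 1]. phi (the
small-world propensity) is 1 for a network with lattice-like clustering and
random-like path length.

The spectral check compares the eigenvalues of the weighted similarity
matrix against symmetry-preserving shuffles of its off-diagonal entries:
an unstructured matrix keeps all eigenvalues inside the shuffled bulk,
whereas planted modules push eigenvalues outside it.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np

from .io import SignedNetwork, SimilarityMatrix

__all__ = [
    "GraphIndicators",
    "SpectrumResult",
    "basic_indicators",
    "clustering_and_path",
    "reference_networks",
    "small_world_measures",
    "graph_indicators",
    "spectrum_vs_shuffled",
]


@dataclass
class GraphIndicators:
    """The indicator set; reference-dependent fields are None until filled."""

    mean_degree: float
    degree_ratio: float          # <k^2>/<k>^2
    modularity: float
    assortativity: float
    clustering: float | None = None
    path_length: float | None = None
    C_rand: float | None = None
    L_rand: float | None = None
    C_latt: float | None = None
    L_latt: float | None = None
    C_norm: float | None = None  # C~
    L_norm: float | None = None  # L~
    small_world_index: float | None = None
    delta_C: float | None = None
    delta_L: float | None = None
    propensity: float | None = None  # phi

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SpectrumResult:
    """Eigenvalues of the weighted matrix vs a shuffled ensemble."""

    eigenvalues: np.ndarray          # original, sorted descending
    shuffled_eigenvalues: np.ndarray  # (n_shuffles, N)
    bulk_min: float
    bulk_max: float
    n_above_bulk: int
    n_below_bulk: int

    @property
    def n_outliers(self) -> int:
        return self.n_above_bulk + self.n_below_bulk


def _unsigned_graph(net: SignedNetwork) -> nx.Graph:
    g = nx.from_numpy_array(net.unsigned_adjacency)
    return g


def _mean_path_length_lcc(g: nx.Graph) -> float:
    """Mean unweighted shortest-path length over the largest component."""
    if g.number_of_edges() == 0:
        raise ValueError("path length undefined on an edgeless graph")
    comp = max(nx.connected_components(g), key=len)
    return nx.average_shortest_path_length(g.subgraph(comp))


def basic_indicators(net: SignedNetwork, seed: int = 0) -> GraphIndicators:
    """Mean degree, degree ratio, modularity, assortativity.

    Modularity uses a greedy (CNM) modularity-maximizing partition of the
    absolute-weight graph; the algorithm is deterministic, the seed is
    accepted for interface stability and echoed into reports.
    """
    if net.n_nodes < 2 or net.n_edges == 0:
        raise ValueError("indicators undefined on single-node or edgeless networks")
    g = _unsigned_graph(net)
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    k = degrees.mean()
    ratio = float((degrees**2).mean() / k**2)
    r = float(nx.degree_pearson_correlation_coefficient(g))
    g_abs = nx.from_numpy_array(np.abs(net.weights))
    communities = nx.community.greedy_modularity_communities(g_abs, weight="weight")
    q = float(nx.community.modularity(g_abs, communities, weight="weight"))
    return GraphIndicators(mean_degree=float(k), degree_ratio=ratio, modularity=q, assortativity=r)


def clustering_and_path(net: SignedNetwork) -> tuple[float, float]:
    """Mean local clustering C and mean shortest-path length L.

    Both are computed on the unsigned, unweighted graph; nodes of degree < 2
    contribute 0 to C, and L averages over the largest connected component.
    """
    g = _unsigned_graph(net)
    c = float(nx.average_clustering(g, count_zeros=True))
    ell = _mean_path_length_lcc(g)
    return c, ell


def _even_lattice_degree(k: float) -> int:
    k_even = int(round(k / 2.0)) * 2
    return max(k_even, 2)


def reference_networks(
    net: SignedNetwork, n_realizations: int = 5, seed: int = 0
) -> tuple[float, float, float, float]:
    """(C_rand, L_rand, C_latt, L_latt) for matched references.

    The random reference is an ensemble of uniform G(N, M) graphs with the
    same node and edge count (density-matched, not degree-matched); the
    lattice reference is the ring lattice in which every node links to its
    round(k) nearest neighbours, k forced even.
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    n, m = net.n_nodes, net.n_edges
    k = 2.0 * m / n
    if k < 2:
        raise ValueError("mean degree < 2: ring-lattice reference undefined")
    c_rands, l_rands = [], []
    for r in range(n_realizations):
        g = nx.gnm_random_graph(n, m, seed=seed + r)
        c_rands.append(nx.average_clustering(g, count_zeros=True))
        l_rands.append(_mean_path_length_lcc(g))
    lattice = nx.watts_strogatz_graph(n, _even_lattice_degree(k), 0.0)
    c_latt = float(nx.average_clustering(lattice, count_zeros=True))
    l_latt = _mean_path_length_lcc(lattice)
    return float(np.mean(c_rands)), float(np.mean(l_rands)), c_latt, l_latt


def small_world_measures(
    C: float, L: float, references: tuple[float, float, float, float]
) -> dict:
    """Normalized C~/L~, small-world index SW, deviations, and propensity phi."""
    c_rand, l_rand, c_latt, l_latt = references
    if c_latt == c_rand or l_latt == l_rand:
        raise ValueError("degenerate references: lattice and random values coincide")
    c_norm = (C - c_rand) / (c_latt - c_rand)
    l_norm = (L - l_rand) / (l_latt - l_rand)
    sw = (C / c_rand) / (L / l_rand)
    delta_c = float(np.clip((c_latt - C) / (c_latt - c_rand), 0.0, 1.0))
    delta_l = float(np.clip((L - l_rand) / (l_latt - l_rand), 0.0, 1.0))
    phi = 1.0 - np.sqrt((delta_c**2 + delta_l**2) / 2.0)
    return {
        "C_norm": float(c_norm),
        "L_norm": float(l_norm),
        "small_world_index": float(sw),
        "delta_C": delta_c,
        "delta_L": delta_l,
        "propensity": float(phi),
    }


def graph_indicators(
    net: SignedNetwork, n_realizations: int = 5, seed: int = 0
) -> GraphIndicators:
    """All indicators including small-world normalization in one pass."""
    ind = basic_indicators(net, seed=seed)
    C, L = clustering_and_path(net)
    refs = reference_networks(net, n_realizations=n_realizations, seed=seed)
    sw = small_world_measures(C, L, refs)
    ind.clustering, ind.path_length = C, L
    ind.C_rand, ind.L_rand, ind.C_latt, ind.L_latt = refs
    ind.C_norm = sw["C_norm"]
    ind.L_norm = sw["L_norm"]
    ind.small_world_index = sw["small_world_index"]
    ind.delta_C = sw["delta_C"]
    ind.delta_L = sw["delta_L"]
    ind.propensity = sw["propensity"]
    return ind


def spectrum_vs_shuffled(
    sim: SimilarityMatrix, n_shuffles: int = 10, seed: int = 0
) -> SpectrumResult:
    """Eigenvalues of the weighted matrix vs symmetry-preserving shuffles.

    Each shuffle permutes the upper-triangle off-diagonal entries and
    mirrors them, preserving the weight multiset and symmetry; the bulk is
    the [min, max] envelope of all shuffled eigenvalues.
    """
    values = sim.values
    n = values.shape[0]
    if n < 3:
        raise ValueError("need at least 3 genes")
    rng = np.random.default_rng(seed)
    orig = np.sort(np.linalg.eigvalsh(values))[::-1]
    iu = np.triu_indices(n, k=1)
    entries = values[iu]
    shuffled_eigs = np.empty((n_shuffles, n))
    for s in range(n_shuffles):
        perm = rng.permutation(entries.size)
        mat = np.zeros_like(values)
        mat[iu] = entries[perm]
        mat = mat + mat.T
        shuffled_eigs[s] = np.sort(np.linalg.eigvalsh(mat))[::-1]
    bulk_min = float(shuffled_eigs.min())
    bulk_max = float(shuffled_eigs.max())
    return SpectrumResult(
        eigenvalues=orig,
        shuffled_eigenvalues=shuffled_eigs,
        bulk_min=bulk_min,
        bulk_max=bulk_max,
        n_above_bulk=int(np.count_nonzero(orig > bulk_max)),
        n_below_bulk=int(np.count_nonzero(orig < bulk_min)),
    )
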