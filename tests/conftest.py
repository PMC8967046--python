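"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from genebalance.io import SignedNetwork, SimilarityMatrix, threshold_network


def net_from_weights(weights: np.ndarray, threshold: float = 0.0) -> SignedNetwork:
    """Build a SignedNetwork from a symmetric weight matrix (zeros = no edge)."""
    n = weights.shape[0]
    sim = SimilarityMatrix(values=weights, gene_ids=tuple(f"g{i}" for i in range(n)))
    return threshold_network(sim, threshold)


def random_signed_weights(n: int, rng: np.random.Generator, p_edge: float = 0.6) -> np.ndarray:
    """Random symmetric weight matrix with signed entries in [-1, 1]."""
    w = rng.uniform(-1.0, 1.0, size=(n, n))
    mask = rng.random((n, n)) < p_edge
    w = np.where(mask, w, 0.0)
    w = np.triu(w, k=1)
    return w + w.T


def brute_force_census(net: SignedNetwork) -> tuple[int, int, int, int]:
    """Per-type triangle counts by exhaustive loop over all node triples."""
    a = net.signed_adjacency
    n = net.n_nodes
    counts = [0, 0, 0, 0]
    for i in range(n):
        for j in range(i + 1, n):
            if a[i, j] == 0:
                continue
            for k in range(j + 1, n):
                if a[j, k] == 0 or a[i, k] == 0:
                    continue
                n_neg = int(a[i, j] < 0) + int(a[j, k] < 0) + int(a[i, k] < 0)
                counts[3 - n_neg] += 1
    return tuple(counts)


def brute_force_energy(net: SignedNetwork) -> float:
    """Network energy by exhaustive triple loop over the weight matrix."""
    w = net.weights
    n = net.n_nodes
    total, delta_w = 0.0, 0.0
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                p = w[i, j] * w[j, k] * w[i, k]
                if p != 0.0:
                    total += p
                    delta_w += abs(p)
    return -total / delta_w


@pytest.fixture(scope="session")
def planted_similarity():
    """A small planted-module similarity matrix shared across tests."""
    from genebalance.synthetic import ProfileModel, generate_profiles, profiles_to_similarity

    model = ProfileModel(
        n_genes=60,
        n_modules=3,
        profile_length=500,
        within_module_corr=0.6,
        between_module_corr=-0.2,
        seed=7,
    )
    profiles = generate_profiles(model)
    return profiles, profiles_to_similarity(profiles)
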