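"""Energy-energy mixing pattern of triads connected through one shared link.

The energy landscape treats triads individually; the mixing pattern asks
how they are organized globally. For every unordered pair of distinct
triangles sharing exactly one edge (equivalently, exactly two nodes), the
pair is routed to the block of its two triad types and binned by each
triad's position in its type's energy-sorted spectrum. The result is a
4 x 4 grid of B x B blocks on a log10(1 + count) scale: dense blocks mean
that triads of those types (and energy ranks) frequently share links,
all-zero blocks mean they sit isolated.

Counting convention: pairs are accumulated as ordered occurrences, so each
unordered pair contributes once to block (type_a, type_b) and once to
block (type_b, type_a). This makes block (a, b) the exact transpose of
block (b, a), keeps same-type blocks symmetric, and makes the grid total
equal twice the number of unordered link-sharing pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Iterator

import numpy as np

from .io import SignedNetwork
from .triads import EnergyResult

__all__ = [
    "MixingMatrix",
    "link_sharing_pairs",
    "mixing_matrix",
    "mixing_from_network",
    "isolation_fraction",
]

# Display order of triad types along the grid axes, following the
# strongly-balanced-first convention: T3, T1, T2, T0.
TYPE_ORDER = (3, 1, 2, 0)


@dataclass(frozen=True)
class MixingMatrix:
    """4x4 grid of B x B rank-binned blocks, log10(1 + ordered pair count)."""

    blocks: np.ndarray          # (4, 4, B, B) log10(1+count), TYPE_ORDER axes
    raw_counts: np.ndarray      # (4, 4, B, B) ordered-occurrence counts
    bin_edges: tuple[np.ndarray, ...]  # energy values at rank-bin boundaries, per type
    B: int
    type_order: tuple[int, int, int, int] = TYPE_ORDER

    @property
    def total_pairs(self) -> int:
        """Number of unordered link-sharing triangle pairs (grid total / 2)."""
        return int(round(self.raw_counts.sum())) // 2

    def grid(self) -> np.ndarray:
        """The merged (4B x 4B) log-scale matrix, blocks in type order."""
        b = self.B
        out = np.zeros((4 * b, 4 * b))
        for a in range(4):
            for c in range(4):
                out[a * b : (a + 1) * b, c * b : (c + 1) * b] = self.blocks[a, c]
        return out


def _edge_to_triangles(tris: np.ndarray) -> dict[tuple[int, int], list[int]]:
    edge_map: dict[tuple[int, int], list[int]] = {}
    for t, (i, j, k) in enumerate(tris):
        for e in ((i, j), (j, k), (i, k)):
            edge_map.setdefault((int(e[0]), int(e[1])), []).append(t)
    return edge_map


def link_sharing_pairs(
    energies: EnergyResult, net: SignedNetwork | None = None
) -> Iterator[tuple[int, int, tuple[int, int]]]:
    """Every unordered pair of distinct triangles sharing exactly one edge.

    Yields (triangle_index_a, triangle_index_b, shared_edge) with a < b,
    each pair exactly once. Two distinct triangles can share at most one
    edge, so grouping triangles by edge enumerates each pair once; sharing
    two nodes implies sharing the edge between them, so "exactly one shared
    edge" and "exactly two shared nodes" coincide.
    """
    edge_map = _edge_to_triangles(energies.triangles)
    for edge, members in edge_map.items():
        if len(members) < 2:
            continue
        for a, b in combinations(members, 2):
            yield (a, b, edge)


def _rank_bins(energies: EnergyResult, B: int) -> tuple[np.ndarray, tuple[np.ndarray, ...]]:
    """Equal-width rank bin of each triangle within its type's sorted spectrum."""
    n_tri = len(energies.types)
    bins = np.zeros(n_tri, dtype=np.int64)
    edges: list[np.ndarray] = []
    for t in range(4):
        idx = np.flatnonzero(energies.types == t)
        if idx.size == 0:
            edges.append(np.array([]))
            continue
        order = np.argsort(energies.energies[idx], kind="stable")
        ranks = np.empty(idx.size, dtype=np.int64)
        ranks[order] = np.arange(idx.size)
        bins[idx] = (ranks * B) // idx.size
        sorted_e = energies.energies[idx][order]
        edge_pos = np.minimum((np.arange(B + 1) * idx.size) // B, idx.size - 1)
        edges.append(sorted_e[edge_pos])
    return bins, tuple(edges)


def mixing_matrix(
    pairs: Iterable[tuple[int, int, tuple[int, int]]],
    energies: EnergyResult,
    B: int = 50,
) -> MixingMatrix:
    """Assemble the mixing grid from an explicit iterator of pairs."""
    if B < 2:
        raise ValueError("need at least 2 bins per axis")
    bins, edges = _rank_bins(energies, B)
    type_pos = {t: a for a, t in enumerate(TYPE_ORDER)}
    counts = np.zeros((4, 4, B, B))
    for a, b, _edge in pairs:
        ta, tb = type_pos[int(energies.types[a])], type_pos[int(energies.types[b])]
        ra, rb = bins[a], bins[b]
        counts[ta, tb, ra, rb] += 1
        counts[tb, ta, rb, ra] += 1
    return MixingMatrix(blocks=np.log10(1.0 + counts), raw_counts=counts, bin_edges=edges, B=B)


def mixing_from_network(energies: EnergyResult, B: int = 50) -> MixingMatrix:
    """Fast path: accumulate the grid per shared edge with outer products.

    For an edge contained in triangles with category histogram h (category =
    type x rank-bin), the ordered pair contributions are outer(h, h) minus
    the self-pair diagonal. Equivalent to routing the explicit iterator of
    :func:`link_sharing_pairs` through :func:`mixing_matrix`.
    """
    if B < 2:
        raise ValueError("need at least 2 bins per axis")
    bins, edges = _rank_bins(energies, B)
    type_pos = np.empty(4, dtype=np.int64)
    for a, t in enumerate(TYPE_ORDER):
        type_pos[t] = a
    cat = type_pos[energies.types] * B + bins  # category in [0, 4B)
    n_cat = 4 * B
    G = np.zeros((n_cat, n_cat))
    edge_map = _edge_to_triangles(energies.triangles)
    for members in edge_map.values():
        if len(members) < 2:
            continue
        h = np.bincount(cat[members], minlength=n_cat).astype(float)
        G += np.outer(h, h) - np.diag(h)
    counts = (
        G.reshape(4, B, 4, B).transpose(0, 2, 1, 3)
    )
    return MixingMatrix(blocks=np.log10(1.0 + counts), raw_counts=counts, bin_edges=edges, B=B)


def isolation_fraction(energies: EnergyResult) -> float:
    """Fraction of triangles sharing no link with any other triangle."""
    n_tri = energies.triangles.shape[0]
    if n_tri == 0:
        return float("nan")
    connected = np.zeros(n_tri, dtype=bool)
    for members in _edge_to_triangles(energies.triangles).values():
        if len(members) >= 2:
            connected[members] = True
    return float(np.count_nonzero(~connected)) / n_tri
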