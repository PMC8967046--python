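"""Reading, writing and thresholding of gene-gene similarity matrices.

The raw input of every analysis stage is a square symmetric matrix of
Pearson correlations between genetic-interaction profiles, with entries in
[-1, 1] and a zero diagonal (self-similarity is not an interaction).
Thresholding by absolute weight turns it into a :class:`SignedNetwork`
holding three aligned views: the retained weights, the signed adjacency
A(Sigma) with entries in {-1, 0, +1}, and the unsigned adjacency A(|Sigma|)
with entries in {0, 1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimilarityMatrix",
    "SignedNetwork",
    "MatrixFormatError",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "threshold_network",
    "edge_sign_fractions",
    "write_edge_list",
    "read_edge_list",
]

_SYMMETRY_TOL = 1e-9


class MatrixFormatError(ValueError):
    """Raised when an input matrix violates the similarity-matrix contract."""


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric gene-by-gene similarity matrix with entries in [-1, 1].

    The diagonal is forced to zero on construction: the analyses below are
    about distinct gene pairs, and a unit diagonal would corrupt degrees and
    every trace-based count.
    """

    values: np.ndarray
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise MatrixFormatError(f"similarity matrix must be square, got {values.shape}")
        if values.shape[0] != len(self.gene_ids):
            raise MatrixFormatError("label count does not match matrix size")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise MatrixFormatError("gene_ids must be unique")
        if np.isnan(values).any():
            raise MatrixFormatError("similarity matrix contains missing values")
        asym = np.abs(values - values.T).max() if values.size else 0.0
        if asym > _SYMMETRY_TOL:
            raise MatrixFormatError(f"matrix asymmetry {asym:.3g} exceeds tolerance {_SYMMETRY_TOL}")
        values = (values + values.T) / 2.0
        np.fill_diagonal(values, 0.0)
        if np.abs(values).max(initial=0.0) > 1.0 + 1e-12:
            raise MatrixFormatError("entries must lie in [-1, 1]")
        values.flags.writeable = False
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class SignedNetwork:
    """Thresholded signed network with aligned weighted/signed/unsigned views.

    Attributes
    ----------
    weights:
        Dense symmetric matrix of retained edge weights; zero means no edge.
    signed_adjacency:
        A(Sigma), entries in {-1, 0, +1}: the sign of each retained weight.
    unsigned_adjacency:
        A(|Sigma|), entries in {0, 1}: 1 wherever an edge is retained.
    """

    gene_ids: tuple[str, ...]
    weights: np.ndarray
    signed_adjacency: np.ndarray
    unsigned_adjacency: np.ndarray
    threshold: float

    @property
    def n_nodes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        return int(self.unsigned_adjacency.sum()) // 2

    def edge_index(self) -> tuple[np.ndarray, np.ndarray]:
        """Upper-triangle (i, j) indices of the retained edges, i < j."""
        return np.nonzero(np.triu(self.unsigned_adjacency, k=1))


def read_similarity_matrix(path: str | Path, *, fill_missing: bool = False) -> SimilarityMatrix:
    """Read a labeled tab-separated similarity matrix.

    The first row and first column carry gene labels. Row and column label
    sets must agree; the matrix is realigned to the row-label order if the
    column order differs. Mild asymmetry (<= 1e-9) is averaged away; anything
    larger is an error. Missing entries are rejected unless ``fill_missing``
    replaces them with zero (no functional relation).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.shape[0] != df.shape[1]:
        raise MatrixFormatError(f"matrix in {path} is not square: {df.shape}")
    if set(df.index) != set(df.columns):
        raise MatrixFormatError(f"row and column labels differ in {path}")
    df = df.loc[:, df.index]  # align columns to row order
    if df.isna().any().any():
        if not fill_missing:
            raise MatrixFormatError(f"missing values in {path}; pass fill_missing=True to zero them")
        df = df.fillna(0.0)
    return SimilarityMatrix(values=df.to_numpy(dtype=float), gene_ids=tuple(df.index))


def write_similarity_matrix(sim: SimilarityMatrix, path: str | Path) -> None:
    """Write the labeled TSV dialect consumed by :func:`read_similarity_matrix`."""
    df = pd.DataFrame(sim.values, index=list(sim.gene_ids), columns=list(sim.gene_ids))
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_edge_list(net: SignedNetwork, path: str | Path) -> None:
    """Write retained edges as TSV with columns gene_i, gene_j, weight."""
    ii, jj = net.edge_index()
    df = pd.DataFrame(
        {
            "gene_i": [net.gene_ids[i] for i in ii],
            "gene_j": [net.gene_ids[j] for j in jj],
            "weight": net.weights[ii, jj],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_edge_list(path: str | Path) -> SimilarityMatrix:
    """Read a gene_i/gene_j/weight TSV back into a dense similarity matrix."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_i": str, "gene_j": str})
    genes = sorted(set(df["gene_i"]) | set(df["gene_j"]))
    idx = {g: k for k, g in enumerate(genes)}
    values = np.zeros((len(genes), len(genes)))
    for gi, gj, w in df.itertuples(index=False):
        values[idx[gi], idx[gj]] = w
        values[idx[gj], idx[gi]] = w
    return SimilarityMatrix(values=values, gene_ids=tuple(genes))


def threshold_network(sim: SimilarityMatrix, threshold: float) -> SignedNetwork:
    """Discard weak similarities and build the signed/unsigned adjacencies.

    An edge (i, j) is retained iff ``|w_ij| >= threshold``; exact zeros are
    never edges (no functional relation). Isolated nodes stay in the node
    set so that node counts are threshold-independent.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    keep = np.abs(sim.values) >= threshold
    keep &= sim.values != 0.0
    np.fill_diagonal(keep, False)
    weights = np.where(keep, sim.values, 0.0)
    signed = np.sign(weights).astype(np.int8)
    unsigned = keep.astype(np.int8)
    return SignedNetwork(
        gene_ids=sim.gene_ids,
        weights=weights,
        signed_adjacency=signed,
        unsigned_adjacency=unsigned,
        threshold=float(threshold),
    )


def edge_sign_fractions(net: SignedNetwork) -> tuple[float, float]:
    """Fractions of positive and negative edges; they sum to one."""
    ii, jj = net.edge_index()
    if len(ii) == 0:
        raise ValueError("network has no edges")
    signs = net.signed_adjacency[ii, jj]
    pos = float(np.count_nonzero(signs > 0)) / len(signs)
    return pos, 1.0 - pos
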