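"""Index bookkeeping between square symmetric matrices and edge vectors.

Edges of an n-node undirected graph are stored as the upper triangle in
row-major (i < j) order, giving vectors of length n(n-1)/2.
"""

from __future__ import annotations

import numpy as np


def edge_pairs(n_regions: int) -> np.ndarray:
    """(E, 2) array of node index pairs (i < j) in vector order."""
    iu = np.triu_indices(n_regions, 1)
    return np.column_stack(iu)


def n_edges(n_regions: int) -> int:
    return n_regions * (n_regions - 1) // 2


def to_vector(matrix: np.ndarray) -> np.ndarray:
    """Upper-triangle values of a square matrix in vector order."""
    m = np.asarray(matrix)
    iu = np.triu_indices(m.shape[0], 1)
    return m[iu]


def to_matrix(vector: np.ndarray, n_regions: int, diagonal: float = 0.0) -> np.ndarray:
    """Symmetric square matrix from an edge vector."""
    vec = np.asarray(vector, dtype=float)
    if len(vec) != n_edges(n_regions):
        raise ValueError(
            f"edge vector length {len(vec)} does not match {n_regions} regions"
        )
    out = np.full((n_regions, n_regions), 0.0)
    iu = np.triu_indices(n_regions, 1)
    out[iu] = vec
    out += out.T
    np.fill_diagonal(out, diagonal)
    return out


def edge_index(i: int, j: int, n_regions: int) -> int:
    """Position of edge (i, j) in the vector order."""
    if i == j:
        raise ValueError("self-edges have no vector position")
    if i > j:
        i, j = j, i
    if not (0 <= i < j < n_regions):
        raise ValueError(f"edge ({i},{j}) outside 0..{n_regions - 1}")
    # offset of row i, plus distance past the diagonal
    return i * (2 * n_regions - i - 1) // 2 + (j - i - 1)
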