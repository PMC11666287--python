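"""Symmetric binary K-nearest-neighbor graphs over spot coordinates.

Every graph layer and the spatial-aware regularizer operate on the same
adjacency: ``A[i, j] = 1`` iff j is among i's k nearest spots by Euclidean
distance *or* i is among j's (union symmetrization). Self-edges are never
stored; attention layers add self-loops internally. Distance ties are broken
toward the lower spot index so graphs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["SpatialGraph", "build_knn_graph", "join_graphs"]


@dataclass
class SpatialGraph:
    adjacency: np.ndarray
    k: int

    def __post_init__(self):
        A = np.asarray(self.adjacency, dtype=np.float64)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.diagonal(A).any():
            raise ValueError("adjacency must have a zero diagonal")
        if not np.isin(A, (0.0, 1.0)).all():
            raise ValueError("adjacency must be binary")
        self.adjacency = A

    @property
    def n_spots(self) -> int:
        return self.adjacency.shape[0]

    @property
    def neighbor_sets(self) -> list[np.ndarray]:
        """Per-spot neighbor index arrays R_i = {j : A[i, j] = 1}."""
        return [np.flatnonzero(row) for row in self.adjacency]

    def edge_list(self) -> np.ndarray:
        """Directed edge list (both orientations), shape (n_edges, 2)."""
        src, dst = np.nonzero(self.adjacency)
        return np.column_stack([src, dst])

    def save_edge_list(self, path) -> None:
        np.savetxt(path, self.edge_list(), fmt="%d", delimiter="\t",
                   header="src\tdst", comments="")


def build_knn_graph(coordinates: np.ndarray, k: int) -> SpatialGraph:
    """Union-symmetrized KNN adjacency over 2-D coordinates.

    Exact all-pairs distances; ties at the k-th neighbor resolved toward the
    lower index. Duplicate coordinates are permitted.
    """
    coords = np.asarray(coordinates, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ValueError("need at least 2 spots with 2-D coordinates")
    if not np.isfinite(coords).all():
        raise ValueError("coordinates must be finite")
    n = coords.shape[0]
    k = int(k)
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of spots ({n})")
    D = cdist(coords, coords)
    np.fill_diagonal(D, np.inf)  # self never a neighbor candidate
    idx = np.arange(n)
    A = np.zeros((n, n))
    for i in range(n):
        # stable order: primary key distance, secondary key index
        order = np.lexsort((idx, D[i]))[:k]
        A[i, order] = 1.0
    A = np.maximum(A, A.T)  # union rule: A_ij = A_ji = 1
    return SpatialGraph(A, k)


def join_graphs(graphs: list[SpatialGraph], coordinates: list[np.ndarray] | None = None,
                mode: str = "block", k: int | None = None) -> SpatialGraph:
    """Combine per-sample graphs into one joint graph.

    ``mode="block"`` stacks the adjacencies block-diagonally (samples stay
    disconnected). ``mode="cross"`` rebuilds a KNN graph on the concatenated,
    pre-aligned coordinates, which requires ``coordinates`` and ``k``.
    """
    if not graphs:
        raise ValueError("need at least one graph")
    if mode == "block":
        n = sum(g.n_spots for g in graphs)
        A = np.zeros((n, n))
        off = 0
        for g in graphs:
            A[off:off + g.n_spots, off:off + g.n_spots] = g.adjacency
            off += g.n_spots
        return SpatialGraph(A, max(g.k for g in graphs))
    if mode == "cross":
        if coordinates is None:
            raise ValueError("cross mode needs the per-sample coordinates")
        coords = np.concatenate([np.asarray(c) for c in coordinates], axis=0)
        return build_knn_graph(coords, k if k is not None else graphs[0].k)
    raise ValueError(f"unknown mode {mode!r}")
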