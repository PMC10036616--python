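"""Per-patient patch graphs and graph utilities.

Each core's patch grid is wired with 4-adjacency plus a self-loop per node;
a patient's cores form disconnected components of one graph (edges never
bridge physically unrelated cores).  Coarsening to the neighborhood graph
uses the soft-assignment quadratic form ``S^T A S``, which reduces to plain
edge counting for one-hot assignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .patches import PatchSet


@dataclass
class PatchGraph:
    """4-adjacency + self-loop graph over a patient's patches."""

    adjacency: sparse.csr_matrix   # L x L, symmetric, unit diagonal
    coords: np.ndarray             # L x 3 (core index, row, col)
    grid_shapes: list              # core index -> (rows, cols)

    @property
    def L(self) -> int:
        return self.adjacency.shape[0]

    def neighbors(self, node: int) -> np.ndarray:
        """Neighbor list including the self-loop."""
        if not 0 <= node < self.L:
            raise IndexError(f"node {node} out of range (L={self.L})")
        return self.adjacency.indices[
            self.adjacency.indptr[node]:self.adjacency.indptr[node + 1]]

    def degree(self, node: int) -> int:
        return len(self.neighbors(node))

    def normalized_adjacency(self) -> sparse.csr_matrix:
        """Row-normalized adjacency (self-loop included) for aggregation."""
        deg = np.asarray(self.adjacency.sum(axis=1)).ravel()
        inv = sparse.diags(1.0 / deg)
        return (inv @ self.adjacency).tocsr()


def build_patch_graph(patchset: PatchSet) -> PatchGraph:
    """4-adjacency within each core + self-loops; cores stay disconnected."""
    coords = patchset.coords
    keys = [tuple(c) for c in coords]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate patch coordinates in patch set")
    index = {k: i for i, k in enumerate(keys)}
    rows, cols = [], []
    for i, (core, r, c) in enumerate(coords):
        rows.append(i)
        cols.append(i)  # self-loop
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            j = index.get((core, r + dr, c + dc))
            if j is not None:
                rows.append(i)
                cols.append(j)
    data = np.ones(len(rows))
    A = sparse.csr_matrix((data, (rows, cols)),
                          shape=(patchset.L, patchset.L))
    return PatchGraph(adjacency=A, coords=np.asarray(coords),
                      grid_shapes=list(patchset.grid_shapes))


def k_hop_nodes(graph: PatchGraph, node: int, K: int) -> set:
    """Nodes reachable within ``K`` edges, excluding ``node`` itself.

    Self-loops contribute no new nodes; an interior grid node at K=2 has
    exactly 12 such neighbors.
    """
    if K < 0:
        raise ValueError("K must be >= 0")
    if not 0 <= node < graph.L:
        raise IndexError(f"node {node} out of range (L={graph.L})")
    frontier = {node}
    seen = {node}
    for _ in range(K):
        nxt = set()
        for u in frontier:
            nxt.update(int(v) for v in graph.neighbors(u))
        frontier = nxt - seen
        seen |= frontier
    seen.discard(node)
    return seen


def coarsen_adjacency(A, S: np.ndarray) -> np.ndarray:
    """Weighted coarse adjacency ``S^T A S`` (diagonal retained)."""
    S = np.asarray(S, dtype=float)
    if sparse.issparse(A):
        if A.shape[0] != S.shape[0]:
            raise ValueError(
                f"A is {A.shape} but S has {S.shape[0]} rows")
        return np.asarray(S.T @ (A @ S))
    A = np.asarray(A, dtype=float)
    if A.shape[0] != A.shape[1] or A.shape[0] != S.shape[0]:
        raise ValueError(f"shape mismatch: A {A.shape}, S {S.shape}")
    return S.T @ A @ S
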