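"""The epsilon-neighborhood similarity graph.

An edge joins two items exactly when their distance d is strictly below
epsilon. In similarity mode the edge carries weight w = 1 - d, so weights
lie in (1 - epsilon, 1]; binary mode (w = 1) serves generic metrics where
distances can exceed 1. Items with no retained edge stay in the graph as
isolated vertices and later become singleton OTUs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc

from .distances import SparseDistanceMatrix
from .io import MpickDataError, atomic_write

__all__ = [
    "NeighborhoodGraph",
    "build_graph",
    "connected_components",
    "induced_subgraph",
    "write_edge_list",
]


@dataclass
class NeighborhoodGraph:
    """Undirected weighted graph: vertices, edge arrays (i < j), weights."""

    vertices: list[str]
    edge_i: np.ndarray
    edge_j: np.ndarray
    weights: np.ndarray
    epsilon: float
    weight_mode: str = "similarity"
    _adj: list | None = field(default=None, repr=False, compare=False)

    @property
    def n(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.weights)

    @property
    def total_weight(self) -> float:
        """m, the sum of edge weights."""
        return float(self.weights.sum())

    @property
    def degrees(self) -> np.ndarray:
        """k_i, the sum of weights on edges incident to each vertex."""
        k = np.zeros(self.n)
        np.add.at(k, self.edge_i, self.weights)
        np.add.at(k, self.edge_j, self.weights)
        return k

    def adjacency(self) -> list[list[tuple[int, float]]]:
        """Neighbor lists [(j, w), ...] per vertex (cached)."""
        if self._adj is None:
            adj: list[list[tuple[int, float]]] = [[] for _ in range(self.n)]
            for i, j, w in zip(self.edge_i, self.edge_j, self.weights):
                adj[int(i)].append((int(j), float(w)))
                adj[int(j)].append((int(i), float(w)))
            self._adj = adj
        return self._adj

    def index(self) -> dict[str, int]:
        return {v: k for k, v in enumerate(self.vertices)}


def build_graph(
    dm: SparseDistanceMatrix, epsilon: float, weight_mode: str = "similarity"
) -> NeighborhoodGraph:
    """Retain exactly the pairs with d < epsilon (strict).

    similarity mode: w = 1 - d (requires epsilon <= 1);
    binary mode: w = 1 for every retained edge.
    """
    if epsilon <= 0:
        raise MpickDataError(f"epsilon must be positive, got {epsilon}")
    if weight_mode not in ("similarity", "binary"):
        raise MpickDataError(f"unknown weight mode: {weight_mode!r}")
    if weight_mode == "similarity" and epsilon > 1:
        raise MpickDataError(
            "similarity weights 1 - d require epsilon <= 1; "
            "use weight_mode='binary' for larger epsilon"
        )
    ei, ej, w = [], [], []
    for (i, j), d in dm.pairs.items():
        if d < epsilon:
            ei.append(i)
            ej.append(j)
            w.append(1.0 - d if weight_mode == "similarity" else 1.0)
    return NeighborhoodGraph(
        vertices=list(dm.labels),
        edge_i=np.asarray(ei, dtype=np.int64),
        edge_j=np.asarray(ej, dtype=np.int64),
        weights=np.asarray(w, dtype=np.float64),
        epsilon=epsilon,
        weight_mode=weight_mode,
    )


def connected_components(g: NeighborhoodGraph) -> list[list[str]]:
    """Maximal connected vertex sets, ordered by smallest vertex position.

    Isolated vertices come back as singleton components.
    """
    if g.n == 0:
        return []
    data = np.ones(g.n_edges)
    mat = coo_matrix((data, (g.edge_i, g.edge_j)), shape=(g.n, g.n))
    n_comp, member = _cc(mat, directed=False)
    comps: dict[int, list[int]] = {}
    for idx, c in enumerate(member):
        comps.setdefault(int(c), []).append(idx)
    ordered = sorted(comps.values(), key=lambda vs: vs[0])
    return [[g.vertices[i] for i in vs] for vs in ordered]


def induced_subgraph(g: NeighborhoodGraph, vertex_subset) -> NeighborhoodGraph:
    """Subgraph on `vertex_subset` keeping edges with both endpoints inside.

    m and the degrees are implicitly recomputed (they are derived values).
    """
    index = g.index()
    subset = list(vertex_subset)
    unknown = [v for v in subset if v not in index]
    if unknown:
        raise MpickDataError(f"unknown vertices in subset: {unknown[:5]}")
    if not subset:
        raise MpickDataError("empty vertex subset")
    keep = sorted(index[v] for v in set(subset))
    new_pos = {old: new for new, old in enumerate(keep)}
    mask = np.fromiter(
        (int(i) in new_pos and int(j) in new_pos for i, j in zip(g.edge_i, g.edge_j)),
        dtype=bool,
        count=g.n_edges,
    )
    ei = np.array([new_pos[int(i)] for i in g.edge_i[mask]], dtype=np.int64)
    ej = np.array([new_pos[int(j)] for j in g.edge_j[mask]], dtype=np.int64)
    return NeighborhoodGraph(
        vertices=[g.vertices[i] for i in keep],
        edge_i=ei,
        edge_j=ej,
        weights=g.weights[mask].copy(),
        epsilon=g.epsilon,
        weight_mode=g.weight_mode,
    )


def write_edge_list(g: NeighborhoodGraph, path) -> None:
    """Debug writer: one "id1 id2 weight" line per edge."""
    with atomic_write(path) as fh:
        for i, j, w in zip(g.edge_i, g.edge_j, g.weights):
            fh.write(f"{g.vertices[int(i)]}\t{g.vertices[int(j)]}\t{w:.10g}\n")
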