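"""Shared fixtures and independent test oracles.

The oracles here deliberately re-derive quantities by definition (double
loops, exhaustive enumeration) and must stay independent of the package's
fast implementations.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from mpick.graph import NeighborhoodGraph

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def make_graph(n: int, edges: list[tuple[int, int, float]]) -> NeighborhoodGraph:
    """Build a NeighborhoodGraph directly from an integer edge list."""
    ei = np.array([min(i, j) for i, j, _ in edges], dtype=np.int64)
    ej = np.array([max(i, j) for i, j, _ in edges], dtype=np.int64)
    w = np.array([w for _, _, w in edges], dtype=np.float64)
    return NeighborhoodGraph(
        vertices=[f"v{k}" for k in range(n)],
        edge_i=ei,
        edge_j=ej,
        weights=w,
        epsilon=1.0,
    )


def random_connected_graph(rng: np.random.Generator, n: int) -> NeighborhoodGraph:
    """Random weighted connected graph: spanning tree plus extra edges."""
    edges: dict[tuple[int, int], float] = {}
    for v in range(1, n):
        u = int(rng.integers(0, v))
        edges[(u, v)] = float(rng.uniform(0.1, 1.0))
    n_extra = int(rng.integers(0, n))
    for _ in range(n_extra):
        u, v = sorted(rng.choice(n, size=2, replace=False).tolist())
        edges[(u, v)] = float(rng.uniform(0.1, 1.0))
    return make_graph(n, [(i, j, w) for (i, j), w in edges.items()])


def modularity_double_loop(g: NeighborhoodGraph, assignment: dict[str, int]) -> float:
    """Literal definition of Q: ordered double sum over all vertex pairs."""
    n = g.n
    W = np.zeros((n, n))
    for i, j, w in zip(g.edge_i, g.edge_j, g.weights):
        W[int(i), int(j)] = w
        W[int(j), int(i)] = w
    k = W.sum(axis=1)
    m = W.sum() / 2.0
    comm = [assignment[v] for v in g.vertices]
    q = 0.0
    for i in range(n):
        for j in range(n):
            if comm[i] == comm[j]:
                q += W[i, j] - k[i] * k[j] / (2 * m)
    return q / (2 * m)


def enumerate_alignment_score(a: str, b: str) -> int:
    """Best global-alignment score by exhaustive path enumeration.

    Scoring: match +1, mismatch -1 (ambiguity codes never match), gap -2,
    terminal gaps free — a gap column is terminal when the other sequence
    is at its boundary (not yet started or already exhausted).
    """
    n, m = len(a), len(b)

    def rec(i: int, j: int) -> int:
        if i == n and j == m:
            return 0
        best = None
        if i < n and j < m:
            match = a[i] == b[j] and a[i] in "ACGT"
            s = (1 if match else -1) + rec(i + 1, j + 1)
            best = s if best is None else max(best, s)
        if i < n:  # a[i] against a gap in b
            s = (0 if j in (0, m) else -2) + rec(i + 1, j)
            best = s if best is None else max(best, s)
        if j < m:  # b[j] against a gap in a
            s = (0 if i in (0, n) else -2) + rec(i, j + 1)
            best = s if best is None else max(best, s)
        return best

    return rec(0, 0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
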