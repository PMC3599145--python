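"""Weighted modularity and its bottom-up (Louvain-style) maximization.

For an undirected weighted graph with total edge weight m, weights w_ij,
and weighted degrees k_i, the modularity of a partition C is

    Q = (1/2m) * sum_ij [ w_ij - k_i k_j / (2m) ] * delta(C_i, C_j)

where the sum runs over ordered vertex pairs (w_ii = 0) and delta is 1 when
i and j share a cluster. The null term k_i k_j / 2m is the weight expected
by chance in a degree-preserving random graph; Q <= 1 always, the
single-cluster partition has Q = 0 exactly, and large Q signals community
structure. The double sum is evaluated through the per-community identity

    Q = sum_c [ S_in(c) / 2m  -  ( S_tot(c) / 2m )^2 ]

with S_in(c) twice the intra-community weight and S_tot(c) the summed
degrees, which is O(edges); equality with the literal double loop is pinned
by the unit tests.

The optimizer is the classic two-phase greedy scheme: start from
singletons, sweep vertices in a seeded shuffled order moving each to the
neighboring community with the largest positive modularity gain, then
aggregate communities into super-vertices (intra-community weight becomes a
self-loop that counts twice in the degree) and repeat until a full pass
yields no move. Given (graph, seed) the result is deterministic: gains must
exceed 1e-12 and ties go to the smallest community id.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .graph import NeighborhoodGraph
from .io import MpickDataError

__all__ = [
    "Partition",
    "modularity_q",
    "louvain_maximize",
    "best_partition_bruteforce",
    "iter_set_partitions",
]

#: minimum modularity gain for a vertex move to be accepted
GAIN_TOL = 1e-12


@dataclass
class Partition:
    """A total vertex -> cluster assignment, optionally with its Q."""

    assignment: dict[str, int]
    q: float | None = None

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for v, c in self.assignment.items():
            out.setdefault(c, []).append(v)
        return out

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))


def _comm_array(g: NeighborhoodGraph, assignment: dict[str, int]) -> np.ndarray:
    missing = [v for v in g.vertices if v not in assignment]
    if missing:
        raise MpickDataError(
            f"partition not total: {len(missing)} unassigned vertices "
            f"(first: {missing[:3]})"
        )
    return np.array([assignment[v] for v in g.vertices])


def modularity_q(g: NeighborhoodGraph, partition) -> float:
    """Modularity Q of a partition on graph g (edgeless graphs rejected)."""
    assignment = partition.assignment if isinstance(partition, Partition) else partition
    m = g.total_weight
    if m <= 0:
        raise MpickDataError("modularity undefined on an edgeless graph")
    comm = _comm_array(g, assignment)
    labels, inv = np.unique(comm, return_inverse=True)
    # S_in as twice the intra-community edge weight
    intra_mask = comm[g.edge_i] == comm[g.edge_j]
    s_in = np.zeros(len(labels))
    np.add.at(s_in, inv[g.edge_i[intra_mask]], 2.0 * g.weights[intra_mask])
    s_tot = np.zeros(len(labels))
    np.add.at(s_tot, inv, g.degrees)
    return float(np.sum(s_in / (2 * m) - (s_tot / (2 * m)) ** 2))


# ---------------------------------------------------------------------------
# Louvain


def _local_moves(adj, loops, k, m, comm, s_tot, order):
    """One or more phase-1 sweeps; returns True if any move was made."""
    improved = False
    moved = True
    while moved:
        moved = False
        for i in order:
            a = comm[i]
            ki = k[i]
            # weights from i to each neighboring community (self-loops excluded)
            wto: dict[int, float] = {}
            for j, w in adj[i]:
                wto[comm[j]] = wto.get(comm[j], 0.0) + w
            s_tot[a] -= ki
            base = wto.get(a, 0.0) / m - s_tot[a] * ki / (2 * m * m)
            best_c, best_gain = a, base
            for c in sorted(wto):
                if c == a:
                    continue
                gain = wto[c] / m - s_tot[c] * ki / (2 * m * m)
                if gain > best_gain + GAIN_TOL or (
                    abs(gain - best_gain) <= GAIN_TOL and c < best_c
                ):
                    best_c, best_gain = c, gain
            if best_c != a and best_gain > base + GAIN_TOL:
                comm[i] = best_c
                s_tot[best_c] += ki
                moved = True
                improved = True
            else:
                comm[i] = a
                s_tot[a] += ki
    return improved


def louvain_maximize(g: NeighborhoodGraph, seed: int = 42) -> Partition:
    """Greedy two-phase modularity maximization; deterministic given seed.

    The result is a local maximum: no single-vertex move to a neighboring
    community increases Q. Raises on edgeless graphs.
    """
    m = g.total_weight
    if m <= 0:
        raise MpickDataError("cannot optimize modularity on an edgeless graph")
    rng = np.random.default_rng(seed)

    # level-local structures; membership maps original vertices to communities
    n = g.n
    adj = [list(nbrs) for nbrs in g.adjacency()]
    loops = np.zeros(n)
    k = g.degrees.astype(float)
    membership = np.arange(n)

    while True:
        comm = np.arange(len(adj))
        s_tot = k.copy()
        order = np.arange(len(adj))
        rng.shuffle(order)
        improved = _local_moves(adj, loops, k, m, comm, s_tot, order)
        if not improved:
            break
        # relabel communities densely, in order of first appearance by vertex index
        relabel: dict[int, int] = {}
        for c in comm:
            if c not in relabel:
                relabel[c] = len(relabel)
        comm = np.array([relabel[c] for c in comm])
        membership = comm[membership]
        nc = len(relabel)
        if nc == len(adj):
            break
        # aggregate: communities become vertices; intra weight -> self-loop
        new_loops = np.zeros(nc)
        new_k = np.zeros(nc)
        agg: list[dict[int, float]] = [dict() for _ in range(nc)]
        for i, nbrs in enumerate(adj):
            ci = comm[i]
            new_loops[ci] += loops[i]
            for j, w in nbrs:
                cj = comm[j]
                if ci == cj:
                    if i < j:
                        new_loops[ci] += w
                else:
                    agg[ci][cj] = agg[ci].get(cj, 0.0) + w
        adj = [sorted(d.items()) for d in agg]
        for c in range(nc):
            new_k[c] = sum(w for _, w in adj[c]) + 2.0 * new_loops[c]
        loops, k = new_loops, new_k

    # densify final community ids over original vertex order
    relabel = {}
    final = []
    for c in membership:
        if c not in relabel:
            relabel[c] = len(relabel)
        final.append(relabel[c])
    assignment = {v: final[i] for i, v in enumerate(g.vertices)}
    part = Partition(assignment=assignment)
    part.q = modularity_q(g, part)
    return part


# ---------------------------------------------------------------------------
# Exhaustive oracle


def iter_set_partitions(items: list) -> Iterator[list[list]]:
    """All set partitions, blocks ordered by their smallest element."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for sub in iter_set_partitions(rest):
        yield [[first]] + sub
        for k in range(len(sub)):
            yield sub[:k] + [[first] + sub[k]] + sub[k + 1 :]


def best_partition_bruteforce(g: NeighborhoodGraph) -> Partition:
    """Global modularity maximum by exhaustive enumeration (|V| <= 12).

    Ties are broken toward fewer clusters, then lexicographically on the
    canonical block form. This is a test oracle, not part of the pipeline.
    """
    if g.n > 12:
        raise MpickDataError(f"brute force limited to 12 vertices, got {g.n}")
    if g.total_weight <= 0:
        raise MpickDataError("modularity undefined on an edgeless graph")
    best = None
    for blocks in iter_set_partitions(list(range(g.n))):
        assignment = {}
        for c, block in enumerate(blocks):
            for i in block:
                assignment[g.vertices[i]] = c
        q = modularity_q(g, assignment)
        key = (-q, len(blocks), tuple(tuple(b) for b in blocks))
        if best is None or _partition_key_better(key, best[0]):
            best = (key, assignment, q)
    return Partition(assignment=best[1], q=best[2])


def _partition_key_better(key, ref) -> bool:
    """Compare (-q, n_blocks, canonical blocks) with a Q tolerance."""
    if key[0] < ref[0] - GAIN_TOL:
        return True
    if key[0] > ref[0] + GAIN_TOL:
        return False
    return key[1:] < ref[1:]
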