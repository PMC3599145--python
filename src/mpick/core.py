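"""The M-pick driver: epsilon-graph, recursive modularity clustering, OTUs.

Pipeline: (1) pairwise distances; (2) epsilon-neighborhood graph keeping
only pairs with d < epsilon; (3) recursive modularity-based clustering.
Each connected component is optimized independently (merging disconnected
parts never raises Q). A component whose optimal partition has Q below the
stopping threshold delta — or collapses to a single cluster — is accepted
as one OTU; otherwise every sub-cluster is re-split into connected
components and recursed. Isolated vertices become singleton OTUs so every
input sequence appears in the output. The recursion both sharpens the
resolution limit of a single global optimization and terminates on
homogeneous sub-graphs, whose maximum modularity stays near zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .distances import SparseDistanceMatrix
from .graph import NeighborhoodGraph, build_graph, connected_components, induced_subgraph
from .io import MpickDataError
from .modularity import Partition, louvain_maximize, modularity_q

__all__ = ["MpickParams", "RecursionNode", "mpick_cluster", "recurse_component"]

#: hard recursion depth cap; a safety valve, never reached on sane inputs
MAX_DEPTH = 50


@dataclass
class MpickParams:
    """Tunable parameters of the method.

    epsilon: distance threshold for the neighborhood graph. Should exceed
        the largest within-taxon neighbor distance; 0.04 suits species-level
        OTUs from 16S data.
    delta: minimum sub-graph modularity required to accept a further split;
        0.1 is the recommended species-level setting.
    seed: controls the optimizer's vertex sweep order only.
    weight_mode: 'similarity' (w = 1 - d) or 'binary' (w = 1).
    precluster_level: optional greedy preclustering distance (e.g. 0.01);
        None disables preclustering.
    """

    epsilon: float = 0.04
    delta: float = 0.1
    seed: int = 42
    weight_mode: str = "similarity"
    precluster_level: float | None = None

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise MpickDataError(f"epsilon must be > 0, got {self.epsilon}")
        if not (0 <= self.delta < 1):
            raise MpickDataError(f"delta must be in [0, 1), got {self.delta}")
        if self.precluster_level is not None and not (0 < self.precluster_level < 1):
            raise MpickDataError(
                f"precluster level must be in (0, 1), got {self.precluster_level}"
            )


@dataclass
class RecursionNode:
    """One node of the recursive clustering tree."""

    vertex_set: tuple[str, ...]
    max_q_found: float | None = None
    children: list["RecursionNode"] = field(default_factory=list)
    is_otu: bool = False
    depth: int = 0

    def leaves(self) -> list["RecursionNode"]:
        if self.is_otu:
            return [self]
        out = []
        for child in self.children:
            out.extend(child.leaves())
        return out


def recurse_component(
    g_sub: NeighborhoodGraph, params: MpickParams, depth: int = 0
) -> RecursionNode:
    """Recursively split one connected sub-graph until homogeneous.

    Stops (single leaf) when the sub-graph is a singleton or edgeless, when
    the optimizer returns a single cluster, or when the optimized partition
    has Q < delta (strict) — the sub-graph then shows no community
    structure worth honoring. Sub-clusters are re-split into connected
    components before recursing, since the optimizer may emit internally
    disconnected clusters and components are independent under Q.
    """
    node = RecursionNode(vertex_set=tuple(g_sub.vertices), depth=depth)
    if g_sub.n == 1 or g_sub.n_edges == 0:
        node.is_otu = True
        return node
    if depth >= MAX_DEPTH:
        warnings.warn(
            f"recursion depth cap {MAX_DEPTH} reached on a component of "
            f"{g_sub.n} vertices; accepting it as one OTU",
            stacklevel=2,
        )
        node.is_otu = True
        return node
    part = louvain_maximize(g_sub, seed=params.seed)
    node.max_q_found = part.q
    if part.n_clusters == 1 or part.q < params.delta:
        node.is_otu = True
        return node
    for cluster_vertices in sorted(part.clusters().values(), key=lambda vs: vs[0]):
        sub = induced_subgraph(g_sub, cluster_vertices)
        for comp in connected_components(sub):
            node.children.append(
                recurse_component(induced_subgraph(sub, comp), params, depth + 1)
            )
    return node


def mpick_cluster(
    dm: SparseDistanceMatrix, params: MpickParams | None = None
) -> tuple[Partition, RecursionNode]:
    """Cluster a distance matrix into OTUs; returns partition + tree.

    Deterministic given (dm, params): cluster ids follow leaf discovery
    order, which is fixed by the component ordering and the seeded
    optimizer.
    """
    if params is None:
        params = MpickParams()
    if len(dm) == 0:
        raise MpickDataError("empty distance matrix")
    g = build_graph(dm, params.epsilon, params.weight_mode)
    root = RecursionNode(vertex_set=tuple(g.vertices))
    for comp in connected_components(g):
        root.children.append(recurse_component(induced_subgraph(g, comp), params))
    assignment: dict[str, int] = {}
    for cid, leaf in enumerate(root.leaves()):
        for v in leaf.vertex_set:
            assignment[v] = cid
    part = Partition(assignment=assignment)
    if g.total_weight > 0:
        part.q = modularity_q(g, part)
    return part, root
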