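"""Model/Results surface over the clustering pipeline.

`MPick` is constructed from data (a distance matrix, sequences, a FASTA
file, or points) plus the method parameters; `fit()` runs the pipeline and
returns an `MPickResults` holding the partition, per-node modularity
diagnostics, and writers. This mirrors the model-object convention of
statistical packages: construction binds data, fitting produces results.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import MpickParams, RecursionNode, mpick_cluster
from .distances import (
    Precluster,
    SparseDistanceMatrix,
    all_pairs,
    expand_partition,
    precluster_greedy,
)
from .io import MpickDataError, otu_name_order, read_fasta, write_otu_table
from .modularity import Partition
from .validation import nmi as _nmi

__all__ = ["MPick", "MPickResults", "run_pipeline"]


class MPick:
    """Threshold-free OTU picking model.

    Parameters
    ----------
    distances : SparseDistanceMatrix
        Pairwise distances between items.
    params : MpickParams, optional
        Method parameters; keyword arguments (epsilon, delta, seed,
        weight_mode, precluster_level) override individual fields.
    """

    def __init__(self, distances: SparseDistanceMatrix, params: MpickParams | None = None, **kw):
        if params is None:
            params = MpickParams(**kw)
        elif kw:
            raise MpickDataError("pass either params or keyword overrides, not both")
        self.distances = distances
        self.params = params
        self.preclusters: list[Precluster] | None = None

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_sequences(cls, records, params: MpickParams | None = None, **kw) -> "MPick":
        """Build from SequenceRecords; computes alignment distances.

        If precluster_level is set, records are greedily preclustered
        first and distances are computed on representatives only.
        """
        p = params if params is not None else MpickParams(**kw)
        preclusters = None
        items = list(records)
        if p.precluster_level is not None:
            preclusters = precluster_greedy(items, p.precluster_level)
            reps = {pc.representative for pc in preclusters}
            items = [r for r in items if r.id in reps]
        if len(items) == 1:
            dm = SparseDistanceMatrix(labels=[items[0].id], pairs={})
        else:
            dm = all_pairs(items, mode="sequence", cutoff=max(p.epsilon, 0.05))
        model = cls(dm, params=p)
        model.preclusters = preclusters
        return model

    @classmethod
    def from_fasta(cls, path, params: MpickParams | None = None, **kw) -> "MPick":
        return cls.from_sequences(read_fasta(path), params=params, **kw)

    @classmethod
    def from_points(cls, points, params: MpickParams | None = None, **kw) -> "MPick":
        """Build from a PointSet with Euclidean distances."""
        p = params if params is not None else MpickParams(**kw)
        dm = all_pairs(points, mode="point", cutoff=p.epsilon)
        return cls(dm, params=p)

    # -- fitting -----------------------------------------------------------

    def fit(self) -> "MPickResults":
        partition, tree = mpick_cluster(self.distances, self.params)
        if self.preclusters is not None:
            full = expand_partition(partition.assignment, self.preclusters)
            partition = Partition(assignment=full, q=partition.q)
        return MPickResults(model=self, partition=partition, tree=tree)


@dataclass
class MPickResults:
    """Fitted clustering: the OTU partition plus recursion diagnostics."""

    model: MPick
    partition: Partition
    tree: RecursionNode

    @property
    def n_otus(self) -> int:
        return self.partition.n_clusters

    @property
    def otu_sizes(self) -> pd.Series:
        names = otu_name_order(self.partition.assignment)
        sizes: dict[str, int] = {}
        for member, cid in self.partition.assignment.items():
            sizes[names[cid]] = sizes.get(names[cid], 0) + 1
        return pd.Series(sizes).sort_index()

    def q_values(self) -> list[float]:
        """Modularity found at each internal recursion node, tree order."""
        out: list[float] = []

        def walk(node: RecursionNode) -> None:
            if node.max_q_found is not None:
                out.append(node.max_q_found)
            for child in node.children:
                walk(child)

        walk(self.tree)
        return out

    @property
    def recursion_depth(self) -> int:
        def depth(node: RecursionNode) -> int:
            return 1 + max((depth(c) for c in node.children), default=0)

        return depth(self.tree) - 1

    def nmi(self, truth) -> float:
        """NMI of the fitted partition against a ground-truth label map."""
        return _nmi(self.partition, truth)

    def to_otu_table(self, path) -> None:
        write_otu_table(self.partition.assignment, path)

    def summary(self) -> str:
        p = self.model.params
        sizes = self.otu_sizes
        qv = self.q_values()
        lines = [
            "M-pick clustering results",
            "=" * 41,
            f"{'items':<28}{len(self.partition.assignment):>13}",
            f"{'OTUs':<28}{self.n_otus:>13}",
            f"{'singleton OTUs':<28}{int((sizes == 1).sum()):>13}",
            f"{'largest OTU':<28}{int(sizes.max()):>13}",
            f"{'epsilon':<28}{p.epsilon:>13g}",
            f"{'delta':<28}{p.delta:>13g}",
            f"{'weight mode':<28}{p.weight_mode:>13}",
            f"{'seed':<28}{p.seed:>13}",
            f"{'recursion depth':<28}{self.recursion_depth:>13}",
            f"{'internal nodes evaluated':<28}{len(qv):>13}",
        ]
        if qv:
            lines.append(f"{'max node modularity':<28}{max(qv):>13.4f}")
        if self.partition.q is not None:
            lines.append(f"{'partition Q on full graph':<28}{self.partition.q:>13.4f}")
        lines.append("=" * 41)
        return "\n".join(lines)


def run_pipeline(
    fasta=None,
    distances: SparseDistanceMatrix | None = None,
    points=None,
    params: MpickParams | None = None,
    out=None,
) -> MPickResults:
    """One-call pipeline over exactly one input kind.

    Accepts a FASTA path, a precomputed SparseDistanceMatrix, or a
    PointSet; optionally writes the OTU table to `out`.
    """
    given = [x is not None for x in (fasta, distances, points)]
    if sum(given) != 1:
        raise MpickDataError("provide exactly one of fasta, distances, points")
    if params is None:
        params = MpickParams()
    if fasta is not None:
        model = MPick.from_fasta(fasta, params=params)
    elif distances is not None:
        model = MPick(distances, params=params)
    else:
        model = MPick.from_points(points, params=params)
    results = model.fit()
    if out is not None:
        results.to_otu_table(out)
    return results
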