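"""Pairwise distances and optional greedy preclustering.

Sequence mode uses a Needleman-Wunsch global alignment (match +1,
mismatch -1, gap -2, terminal gaps free); the distance of a pair is
(mismatched columns + internal gap columns) divided by the number of
alignment columns excluding terminal-gap columns, a fraction in [0, 1].
Ambiguity codes count as mismatches against everything, including
themselves. Point mode uses the Euclidean metric.

Greedy preclustering groups reads at a small distance level (typically 1%)
and hands only one representative per group to the main algorithm, the
standard trick for cutting the O(n^2) alignment cost on large datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from . import _align
from .io import MpickDataError, SequenceRecord

__all__ = [
    "SparseDistanceMatrix",
    "PointSet",
    "Precluster",
    "pairwise_seq_distance",
    "all_pairs",
    "precluster_greedy",
    "expand_partition",
]


@dataclass
class SparseDistanceMatrix:
    """Symmetric pairwise distances, each unordered pair stored once.

    pairs maps (i, j) with i < j (indices into labels) to the distance.
    Absent pairs mean "farther than any epsilon of interest".
    """

    labels: list[str]
    pairs: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise MpickDataError("duplicate labels in distance matrix")
        for (i, j), d in self.pairs.items():
            if not (0 <= i < j < len(self.labels)):
                raise MpickDataError(f"bad pair index ({i}, {j})")
            if d < 0:
                raise MpickDataError(f"negative distance for pair ({i}, {j})")

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, i: int, j: int, default: float = 0.0) -> float:
        if i == j:
            return 0.0
        key = (i, j) if i < j else (j, i)
        return self.pairs.get(key, default)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SparseDistanceMatrix):
            return NotImplemented
        return self.labels == other.labels and self.pairs.keys() == other.pairs.keys() and all(
            abs(self.pairs[k] - other.pairs[k]) <= 1e-9 for k in self.pairs
        )


@dataclass
class PointSet:
    """Labelled points of a common dimension (toy geometric mode)."""

    labels: list[str]
    coordinates: list[list[float]]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.coordinates):
            raise MpickDataError("labels and coordinates differ in length")
        dims = {len(row) for row in self.coordinates}
        if len(dims) > 1:
            raise MpickDataError(f"points have mixed dimensions: {sorted(dims)}")
        if dims and min(dims) < 1:
            raise MpickDataError("points must have dimension >= 1")

    def __len__(self) -> int:
        return len(self.labels)

    def array(self) -> np.ndarray:
        return np.asarray(self.coordinates, dtype=float)


@dataclass
class Precluster:
    representative: str
    members: list[str]


def pairwise_seq_distance(a: SequenceRecord, b: SequenceRecord) -> float:
    """Global-alignment distance fraction between two reads.

    Symmetric by construction: the pair is canonically ordered before the
    (tie-break-sensitive) traceback, so d(a, b) == d(b, a) exactly.
    """
    ea, eb = _align.encode(a.residues), _align.encode(b.residues)
    if a.residues <= b.residues:
        mism, igap, cols, _ = _align.nw_counts(ea, eb)
    else:
        mism, igap, cols, _ = _align.nw_counts(eb, ea)
    return (mism + igap) / cols if cols else 0.0


def _encode_all(records: list[SequenceRecord]):
    lens = np.array([len(r) for r in records], dtype=np.int64)
    seqs = np.zeros((len(records), int(lens.max())), dtype=np.uint8)
    for k, r in enumerate(records):
        seqs[k, : lens[k]] = _align.encode(r.residues)
    order = np.empty(len(records), dtype=np.int64)
    for rank, k in enumerate(sorted(range(len(records)), key=lambda k: records[k].residues)):
        order[k] = rank
    return seqs, lens, order


def all_pairs(items, mode: str = "sequence", cutoff: float | None = None) -> SparseDistanceMatrix:
    """Evaluate every unordered pair; optionally store only d < cutoff.

    `items` is a list of SequenceRecord (mode 'sequence') or a PointSet
    (mode 'point'). A cutoff-limited matrix is sufficient for any later
    epsilon <= cutoff, since absent pairs mean "no edge".
    """
    if cutoff is not None and cutoff <= 0:
        raise MpickDataError(f"cutoff must be positive, got {cutoff}")
    if mode == "sequence":
        records = list(items)
        if len(records) < 2:
            raise MpickDataError("need at least 2 sequences")
        labels = [r.id for r in records]
        if len(set(labels)) != len(labels):
            raise MpickDataError("duplicate sequence ids")
        seqs, lens, order = _encode_all(records)
        flat = _align.all_pairs_seq(seqs, lens, order)
    elif mode == "point":
        ps = items if isinstance(items, PointSet) else PointSet(*items)
        if len(ps) < 2:
            raise MpickDataError("need at least 2 points")
        labels = list(ps.labels)
        flat = pdist(ps.array(), metric="euclidean")
    else:
        raise MpickDataError(f"unknown mode: {mode!r}")
    n = len(labels)
    pairs: dict[tuple[int, int], float] = {}
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            d = float(flat[k])
            k += 1
            if cutoff is None or d < cutoff:
                pairs[(i, j)] = d
    return SparseDistanceMatrix(labels=labels, pairs=pairs)


def precluster_greedy(records: list[SequenceRecord], level: float) -> list[Precluster]:
    """Greedy incremental preclustering at the given distance level.

    Records are processed in decreasing length order (ties by id); each
    joins the first existing representative closer than `level`, else
    founds a new precluster. Preclusters are returned in founding order.
    """
    if not records:
        raise MpickDataError("empty input to precluster_greedy")
    if not (0 < level < 1):
        raise MpickDataError(f"precluster level must be in (0, 1), got {level}")
    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    reps: list[SequenceRecord] = []
    clusters: list[Precluster] = []
    for rec in ordered:
        for rep, pc in zip(reps, clusters):
            if pairwise_seq_distance(rec, rep) < level:
                pc.members.append(rec.id)
                break
        else:
            reps.append(rec)
            clusters.append(Precluster(representative=rec.id, members=[rec.id]))
    return clusters


def expand_partition(
    partition: dict[str, int], preclusters: list[Precluster]
) -> dict[str, int]:
    """Propagate each representative's cluster to all its members."""
    out: dict[str, int] = {}
    for pc in preclusters:
        if pc.representative not in partition:
            raise MpickDataError(
                f"representative {pc.representative!r} missing from partition"
            )
        cid = partition[pc.representative]
        for member in pc.members:
            out[member] = cid
    return out
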