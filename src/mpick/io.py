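"""Readers and writers for every on-disk representation the tool touches.

Formats: FASTA (optionally gzipped), pairwise distance matrices in a sparse
three-column dialect and a square PHYLIP-like dialect, point-coordinate
tables, OTU membership tables, and ground-truth label maps.
"""

from __future__ import annotations

import gzip
import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "MpickDataError",
    "SequenceRecord",
    "read_fasta",
    "read_distances",
    "write_distances",
    "read_points",
    "write_points",
    "write_otu_table",
    "read_labels",
    "write_labels",
    "atomic_write",
]

# IUPAC DNA alphabet after U->T normalization; '-' is not accepted.
IUPAC_DNA = frozenset("ACGTNRYSWKMBDHV")

OTU_TABLE_HEADER = ("member_id", "otu_id")


class MpickDataError(ValueError):
    """Malformed or inconsistent input data (CLI exit code 2)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One amplicon read: a unique identifier plus DNA residues.

    Residues are stored upper-case with U replaced by T. Any IUPAC DNA
    symbol (including ambiguity codes and N) is accepted.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise MpickDataError(f"invalid sequence id: {self.id!r}")
        norm = self.residues.upper().replace("U", "T")
        if len(norm) < 1:
            raise MpickDataError(f"sequence {self.id!r} has empty residues")
        bad = set(norm) - IUPAC_DNA
        if bad:
            raise MpickDataError(
                f"sequence {self.id!r} contains non-IUPAC characters: "
                f"{''.join(sorted(bad))}"
            )
        object.__setattr__(self, "residues", norm)

    def __len__(self) -> int:
        return len(self.residues)


def _open_text(path) -> Iterator[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file (plain or .gz) into SequenceRecords.

    Multi-line bodies are concatenated and input order is preserved.
    Raises MpickDataError on duplicate ids, empty bodies, or content that
    is not FASTA (reported with its line number).
    """
    with _open_text(path) as fh:
        # locate the first non-blank line so parse errors carry a line number
        lineno = 0
        first = None
        pos_lines: list[str] = []
        for line in fh:
            lineno += 1
            pos_lines.append(line)
            if line.strip():
                first = line
                break
        if first is None:
            return []
        if not first.lstrip().startswith(">"):
            raise MpickDataError(
                f"{path}: line {lineno}: expected FASTA header '>' "
                f"but found {first.strip()[:40]!r}"
            )
        rest = fh

        def chained():
            yield from pos_lines
            yield from rest

        records: list[SequenceRecord] = []
        seen: set[str] = set()
        for title, seq in SimpleFastaParser(chained()):
            rid = title.split()[0] if title.split() else ""
            if not seq:
                raise MpickDataError(f"{path}: sequence {rid!r} has an empty body")
            if rid in seen:
                raise MpickDataError(f"{path}: duplicate sequence id {rid!r}")
            seen.add(rid)
            records.append(SequenceRecord(rid, seq))
    return records


def _check_distance(d: float, a: str, b: str, mode: str) -> None:
    if d < 0:
        raise MpickDataError(f"negative distance {d} for pair ({a}, {b})")
    if mode == "sequence" and d > 1:
        raise MpickDataError(
            f"distance {d} for pair ({a}, {b}) outside [0, 1] (sequence mode)"
        )


def read_distances(path, dialect: str = "sparse", mode: str = "sequence"):
    """Read a pairwise distance matrix.

    dialect 'sparse': whitespace-delimited rows "id1 id2 d"; lines starting
    with '#' are comments. Absent pairs mean "beyond any epsilon of
    interest" (no edge), not distance zero.

    dialect 'square': first line is n, then n rows "label d1 ... dn"
    (PHYLIP-like); the matrix must be symmetric with a zero diagonal.
    """
    from .distances import SparseDistanceMatrix

    if dialect not in ("sparse", "square"):
        raise MpickDataError(f"unknown distance dialect: {dialect!r}")
    labels: list[str] = []
    index: dict[str, int] = {}
    pairs: dict[tuple[int, int], float] = {}

    def label_idx(lab: str) -> int:
        if lab not in index:
            index[lab] = len(labels)
            labels.append(lab)
        return index[lab]

    with _open_text(path) as fh:
        if dialect == "sparse":
            for lineno, line in enumerate(fh, 1):
                s = line.strip()
                if not s or s.startswith("#"):
                    continue
                parts = s.split()
                if len(parts) != 3:
                    raise MpickDataError(
                        f"{path}: line {lineno}: expected 'id1 id2 d', got {s!r}"
                    )
                a, b, ds = parts
                try:
                    d = float(ds)
                except ValueError:
                    raise MpickDataError(
                        f"{path}: line {lineno}: non-numeric distance {ds!r}"
                    ) from None
                _check_distance(d, a, b, mode)
                if a == b:
                    if d != 0.0:
                        raise MpickDataError(
                            f"{path}: line {lineno}: self-pair {a!r} with d={d}"
                        )
                    label_idx(a)
                    continue
                i, j = label_idx(a), label_idx(b)
                key = (i, j) if i < j else (j, i)
                if key in pairs and abs(pairs[key] - d) > 1e-9:
                    raise MpickDataError(
                        f"{path}: line {lineno}: conflicting entries for pair "
                        f"({a}, {b}): {pairs[key]} vs {d}"
                    )
                pairs[key] = d
        else:  # square
            header = fh.readline()
            try:
                n = int(header.split()[0])
            except (ValueError, IndexError):
                raise MpickDataError(
                    f"{path}: line 1: expected sequence count, got {header.strip()!r}"
                ) from None
            rows: list[list[float]] = []
            for lineno, line in enumerate(fh, 2):
                s = line.strip()
                if not s:
                    continue
                parts = s.split()
                if len(parts) != n + 1:
                    raise MpickDataError(
                        f"{path}: line {lineno}: expected label plus {n} values"
                    )
                label_idx(parts[0])
                rows.append([float(x) for x in parts[1:]])
            if len(rows) != n:
                raise MpickDataError(f"{path}: expected {n} matrix rows, got {len(rows)}")
            for i in range(n):
                if rows[i][i] != 0.0:
                    raise MpickDataError(
                        f"{path}: nonzero diagonal for {labels[i]!r}: {rows[i][i]}"
                    )
                for j in range(i + 1, n):
                    if abs(rows[i][j] - rows[j][i]) > 1e-9:
                        raise MpickDataError(
                            f"{path}: asymmetric entries for pair "
                            f"({labels[i]}, {labels[j]})"
                        )
                    _check_distance(rows[i][j], labels[i], labels[j], mode)
                    pairs[(i, j)] = rows[i][j]
    return SparseDistanceMatrix(labels=labels, pairs=pairs)


def write_distances(dm, path, dialect: str = "sparse") -> None:
    """Write a SparseDistanceMatrix in either dialect.

    The square dialect requires a complete matrix (every pair stored).
    """
    if dialect not in ("sparse", "square"):
        raise MpickDataError(f"unknown distance dialect: {dialect!r}")
    n = len(dm.labels)
    if dialect == "square" and len(dm.pairs) != n * (n - 1) // 2:
        raise MpickDataError(
            "square dialect requires a complete matrix "
            f"({len(dm.pairs)} of {n * (n - 1) // 2} pairs stored)"
        )
    with atomic_write(path) as fh:
        if dialect == "sparse":
            for (i, j), d in sorted(dm.pairs.items()):
                fh.write(f"{dm.labels[i]}\t{dm.labels[j]}\t{d:.10g}\n")
        else:
            fh.write(f"{n}\n")
            for i in range(n):
                row = [dm.get(i, j) for j in range(n)]
                fh.write(dm.labels[i] + "\t" + "\t".join(f"{d:.10g}" for d in row) + "\n")


def read_points(path):
    """Read a point table: whitespace rows "label x1 x2 ...", '#' comments."""
    from .distances import PointSet

    labels: list[str] = []
    coords: list[list[float]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) < 2:
                raise MpickDataError(
                    f"{path}: line {lineno}: expected 'label x1 [x2 ...]'"
                )
            labels.append(parts[0])
            try:
                coords.append([float(x) for x in parts[1:]])
            except ValueError:
                raise MpickDataError(
                    f"{path}: line {lineno}: non-numeric coordinate"
                ) from None
    if len(set(labels)) != len(labels):
        raise MpickDataError(f"{path}: duplicate point labels")
    return PointSet(labels=labels, coordinates=coords)


def write_points(ps, path) -> None:
    with atomic_write(path) as fh:
        for lab, row in zip(ps.labels, ps.coordinates):
            fh.write(lab + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")


def otu_name_order(partition: dict[str, int]) -> dict[int, str]:
    """Map internal cluster ids to OTU_xxxxxx names.

    Names are assigned in decreasing cluster-size order; ties broken by the
    lexicographically smallest member id, so output is deterministic.
    """
    clusters: dict[int, list[str]] = {}
    for member, cid in partition.items():
        clusters.setdefault(cid, []).append(member)
    order = sorted(clusters, key=lambda c: (-len(clusters[c]), min(clusters[c])))
    return {cid: f"OTU_{k + 1:06d}" for k, cid in enumerate(order)}


def write_otu_table(partition: dict[str, int], path) -> None:
    """Write the OTU membership table as two-column TSV.

    Byte-deterministic for a fixed partition: OTUs are numbered by
    decreasing size (ties by smallest member id), members sorted within.
    """
    names = otu_name_order(partition)
    rows = sorted(partition.items(), key=lambda kv: (names[kv[1]], kv[0]))
    with atomic_write(path) as fh:
        fh.write("\t".join(OTU_TABLE_HEADER) + "\n")
        for member, cid in rows:
            fh.write(f"{member}\t{names[cid]}\n")


def read_labels(path) -> dict[str, str]:
    """Read a two-column id -> label TSV (ground truth or OTU table).

    A leading "member_id<TAB>otu_id" header line is skipped, so OTU tables
    written by write_otu_table round-trip through this reader.
    """
    entries: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) != 2:
                raise MpickDataError(
                    f"{path}: line {lineno}: expected two columns, got {s!r}"
                )
            rid, lab = parts
            if lineno == 1 and (rid, lab) == OTU_TABLE_HEADER:
                continue
            if rid in entries and entries[rid] != lab:
                raise MpickDataError(
                    f"{path}: line {lineno}: conflicting labels for {rid!r}: "
                    f"{entries[rid]!r} vs {lab!r}"
                )
            entries[rid] = lab
    return entries


def write_labels(entries: dict[str, str], path) -> None:
    with atomic_write(path) as fh:
        for rid in sorted(entries):
            fh.write(f"{rid}\t{entries[rid]}\n")


class atomic_write:
    """Context manager writing to a temp file, renamed into place on success.

    Guarantees no partial output file exists after a failure.
    """

    def __init__(self, path):
        self.path = str(path)
        self._tmp = None

    def __enter__(self):
        d = os.path.dirname(self.path) or "."
        fd, tmp = tempfile.mkstemp(dir=d, prefix=".mpick-tmp-")
        self._tmp = tmp
        self._fh = os.fdopen(fd, "w")
        return self._fh

    def __exit__(self, exc_type, exc, tb):
        self._fh.close()
        if exc_type is None:
            os.replace(self._tmp, self.path)
        else:
            os.unlink(self._tmp)
        return False
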