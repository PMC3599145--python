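"""Seeded generators for every test input the tool needs.

Two regimes are emulated:

* a three-component Gaussian mixture in the plane (the geometric toy mode):
  component means differ along x, components have unequal sizes and
  spreads, so no single distance cut separates them;

* a multi-taxon amplicon dataset: one random ancestor per taxon, all
  ancestors at least a prescribed divergence apart, and reads drawn as the
  ancestor plus i.i.d. substitutions at a small per-site rate. This yields
  small within-taxon and large between-taxon distances — the separability
  regime in which a species-level epsilon threshold is meaningful. No
  indels or chimeras are simulated by default.

Both generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distances import PointSet
from .io import MpickDataError, SequenceRecord

__all__ = ["MixtureSpec", "TaxaSpec", "gen_gaussian_points", "gen_taxa_sequences"]

_BASES = "ACGT"


@dataclass
class MixtureSpec:
    """Gaussian mixture: x-means, per-component sd (all axes), sizes."""

    means_x: tuple[float, ...] = (-0.5, 1.0, 3.0)
    sds: tuple[float, ...] = (0.2, 0.4, 0.6)
    sizes: tuple[int, ...] = (150, 100, 250)
    dimension: int = 2

    def __post_init__(self) -> None:
        if not (len(self.means_x) == len(self.sds) == len(self.sizes)):
            raise MpickDataError("mixture spec fields differ in length")
        if any(s < 1 for s in self.sizes):
            raise MpickDataError("component sizes must be >= 1")
        if any(sd <= 0 for sd in self.sds):
            raise MpickDataError("component sds must be > 0")
        if self.dimension < 1:
            raise MpickDataError("dimension must be >= 1")


def gen_gaussian_points(
    spec: MixtureSpec | None = None, seed: int = 0
) -> tuple[PointSet, dict[str, str]]:
    """Sample the mixture; labels record the component of origin.

    The first coordinate is centered on the component's x-mean; any
    further coordinates are centered on 0 with the same per-component sd.
    """
    if spec is None:
        spec = MixtureSpec()
    rng = np.random.default_rng(seed)
    labels: list[str] = []
    coords: list[list[float]] = []
    truth: dict[str, str] = {}
    idx = 0
    for comp, (mu, sd, size) in enumerate(zip(spec.means_x, spec.sds, spec.sizes)):
        center = np.zeros(spec.dimension)
        center[0] = mu
        pts = rng.normal(loc=center, scale=sd, size=(size, spec.dimension))
        for row in pts:
            pid = f"p{idx:05d}"
            idx += 1
            labels.append(pid)
            coords.append([float(x) for x in row])
            truth[pid] = f"component_{comp + 1}"
    return PointSet(labels=labels, coordinates=coords), truth


@dataclass
class TaxaSpec:
    """Multi-taxon amplicon dataset specification.

    within_taxon_sub_rate is the expected substitutions per site per read
    (scalar, or one rate per taxon to emulate taxa of varying tightness);
    min_between_taxon_divergence is the smallest allowed pairwise ancestor
    divergence as a site fraction.
    """

    n_taxa: int = 11
    seqs_per_taxon: int | tuple[int, ...] = 100
    seq_length: int = 250
    within_taxon_sub_rate: float | tuple[float, ...] = 0.01
    min_between_taxon_divergence: float = 0.10

    def sizes(self) -> list[int]:
        if isinstance(self.seqs_per_taxon, int):
            return [self.seqs_per_taxon] * self.n_taxa
        return list(self.seqs_per_taxon)

    def rates(self) -> list[float]:
        if isinstance(self.within_taxon_sub_rate, (int, float)):
            return [float(self.within_taxon_sub_rate)] * self.n_taxa
        return [float(r) for r in self.within_taxon_sub_rate]

    def __post_init__(self) -> None:
        if self.n_taxa < 1:
            raise MpickDataError("n_taxa must be >= 1")
        sizes = self.sizes()
        if len(sizes) != self.n_taxa or any(s < 1 for s in sizes):
            raise MpickDataError("invalid per-taxon sizes")
        rates = self.rates()
        if len(rates) != self.n_taxa:
            raise MpickDataError("need one substitution rate per taxon")
        if not (0 <= self.min_between_taxon_divergence <= 1):
            raise MpickDataError("between-taxon divergence must be in [0, 1]")
        if any(not (0 <= r < self.min_between_taxon_divergence) for r in rates) and (
            self.min_between_taxon_divergence > 0
        ):
            raise MpickDataError(
                "within-taxon rates must satisfy 0 <= rate < between divergence"
            )
        if self.seq_length < 1:
            raise MpickDataError("seq_length must be >= 1")


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    hit = rng.random(len(seq)) < rate
    k = int(hit.sum())
    if k:
        # substitute uniformly among the 3 alternative bases
        out[hit] = (out[hit] + rng.integers(1, 4, k)) % 4
    return out


def _draw_ancestors(spec: TaxaSpec, rng: np.random.Generator) -> np.ndarray:
    """Ancestors mutated off a common root until all pairs are divergent.

    Each ancestor starts as the root mutated at the between-divergence
    rate; any ancestor too close to an earlier one is redrawn, with a
    bounded number of attempts before declaring the spec infeasible.
    """
    L = spec.seq_length
    need = int(np.ceil(spec.min_between_taxon_divergence * L))
    # 3/4 is the saturation divergence of uniform random sequences
    if need > 0.75 * L + 3 * np.sqrt(L):
        raise MpickDataError(
            "between-taxon divergence unreachable at this sequence length"
        )
    root = rng.integers(0, 4, L).astype(np.uint8)
    anc: list[np.ndarray] = []
    for _ in range(spec.n_taxa):
        for attempt in range(200):
            cand = _mutate(root, max(spec.min_between_taxon_divergence, 0.05), rng)
            if all(int((cand != a).sum()) >= need for a in anc):
                anc.append(cand)
                break
        else:
            raise MpickDataError(
                "could not draw sufficiently divergent ancestors after 200 attempts"
            )
    return np.array(anc)


def gen_taxa_sequences(
    spec: TaxaSpec | None = None, seed: int = 0
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Generate reads and their ground-truth taxon labels."""
    if spec is None:
        spec = TaxaSpec()
    rng = np.random.default_rng(seed)
    anc = _draw_ancestors(spec, rng)
    records: list[SequenceRecord] = []
    truth: dict[str, str] = {}
    for t, (size, rate) in enumerate(zip(spec.sizes(), spec.rates())):
        taxon = f"taxon_{t + 1:02d}"
        for r in range(size):
            read = _mutate(anc[t], rate, rng)
            rid = f"t{t + 1:02d}_r{r + 1:04d}"
            records.append(
                SequenceRecord(rid, "".join(_BASES[b] for b in read))
            )
            truth[rid] = taxon
    return records, truth
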