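"""Domain types shared across the homoeolog expression / splicing pipeline.

Coordinate conventions
----------------------
All coordinates are 0-based, half-open ``[start, end)`` in per-gene genomic
space (position 0 is the first base of the gene body on its subgenome).
GTF emission converts to 1-based inclusive.  Short-read ``start``/``end``
are transcript (spliced mRNA) coordinates of the reference isoform; the SNP
calls they carry are genomic positions, which is what every downstream
operation keys on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

BASES = ("A", "C", "G", "T")

#: subgenome labels: blunt snout bream and topmouth culter
BSB = "BSB"
TC = "TC"
SUBGENOMES = (BSB, TC)

#: alternative-splicing event classes
AS_TYPES = ("SE", "RI", "A5SS", "A3SS", "MXE", "AP", "OTHER")
NAMED_AS_TYPES = ("SE", "RI", "A5SS", "A3SS", "MXE", "AP")

TISSUES = ("gonad", "liver", "muscle")
HYBRIDS = ("TBF3", "BTF3")  # TB: TC mother; BT: BSB mother
REPLICATES = (1, 2, 3)


class ConfigError(ValueError):
    """An invalid configuration field."""


class CapabilityError(ValueError):
    """A request the given gene model cannot realize (e.g. MXE on 2 exons)."""


class InputShapeError(ValueError):
    """Structurally malformed input (wrong replicate count, negative counts)."""


class MappingError(ValueError):
    """A coordinate map could not be built or used."""


class StatisticsError(ValueError):
    """Too little data for the requested statistic."""


class IntegrityError(ValueError):
    """Cross-table references that do not resolve (unknown SNP, gene...)."""


class DependencyError(RuntimeError):
    """A pipeline stage was invoked before the stage it depends on."""


def _check_exons(exons: tuple[tuple[int, int], ...]) -> None:
    if len(exons) == 0:
        raise InputShapeError("chain must contain at least one exon")
    prev_end = -1
    for start, end in exons:
        if not (0 <= start < end):
            raise InputShapeError(f"malformed exon interval [{start}, {end})")
        if start < prev_end:
            raise InputShapeError("exons must be sorted and pairwise disjoint")
        prev_end = end


@dataclass(frozen=True)
class ExonChain:
    """One isoform's ordered exon intervals — the unit of AS comparison."""

    gene: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    chain_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InputShapeError(f"strand must be + or -, got {self.strand!r}")
        _check_exons(self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons, as (donor-side, acceptor-side) on +."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def length(self) -> int:
        """Spliced (mRNA) length in bp."""
        return sum(e - s for s, e in self.exons)

    def structure_key(self) -> tuple[tuple[int, int], ...]:
        return self.exons


@dataclass(frozen=True)
class GeneModel:
    """A gene on one subgenome: strand, exon intervals, CDS length."""

    gene_id: str
    subgenome: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_length: int

    def __post_init__(self) -> None:
        if self.subgenome not in SUBGENOMES:
            raise InputShapeError(f"unknown subgenome {self.subgenome!r}")
        if self.strand not in ("+", "-"):
            raise InputShapeError(f"strand must be + or -, got {self.strand!r}")
        _check_exons(self.exons)
        if self.cds_length < 0 or self.cds_length > self.transcript_length:
            raise InputShapeError(
                f"cds_length {self.cds_length} outside [0, transcript length] "
                f"for {self.gene_id}"
            )

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def chain(self, chain_id: str = "ref") -> ExonChain:
        return ExonChain(self.gene_id, self.strand, self.exons, chain_id)


@dataclass(frozen=True)
class OrthologPair:
    """A reciprocal-best-hit pairing of one BSB gene with one TC gene."""

    bsb_gene: str
    tc_gene: str
    score: float
    evalue_like: float

    @property
    def pair_id(self) -> str:
        return f"{self.bsb_gene}|{self.tc_gene}"


@dataclass(frozen=True)
class SpeciesSNP:
    """An aligned column where the two parents carry disjoint allele sets."""

    pair_id: str
    bsb_pos: int
    tc_pos: int
    bsb_alleles: frozenset
    tc_alleles: frozenset
    bsb_coverage: tuple[int, int, int]
    tc_coverage: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.bsb_alleles & self.tc_alleles:
            raise InputShapeError("species SNP allele sets must be disjoint")
        if min(self.bsb_coverage) < 1 or min(self.tc_coverage) < 1:
            raise InputShapeError("species SNP requires coverage >= 1 everywhere")


class CoordMap:
    """Invertible position map between the two genes of an ortholog pair.

    Built from a pairwise alignment; indel columns are recorded and excluded
    from the mapping, so lookups at indel-adjacent positions return ``None``.
    """

    def __init__(
        self,
        pair_id: str,
        bsb_pos: Iterable[int],
        tc_pos: Iterable[int],
        indel_bsb: Iterable[int] = (),
        indel_tc: Iterable[int] = (),
    ) -> None:
        self.pair_id = pair_id
        self.bsb_pos = np.asarray(list(bsb_pos), dtype=np.int64)
        self.tc_pos = np.asarray(list(tc_pos), dtype=np.int64)
        if self.bsb_pos.shape != self.tc_pos.shape:
            raise MappingError("aligned column lists differ in length")
        if self.bsb_pos.size and (
            np.any(np.diff(self.bsb_pos) <= 0) or np.any(np.diff(self.tc_pos) <= 0)
        ):
            raise MappingError("aligned columns must be strictly increasing")
        self.indel_bsb = frozenset(int(p) for p in indel_bsb)
        self.indel_tc = frozenset(int(p) for p in indel_tc)

    def __len__(self) -> int:
        return int(self.bsb_pos.size)

    @staticmethod
    def _lookup(keys: np.ndarray, values: np.ndarray, pos: int) -> int | None:
        i = int(np.searchsorted(keys, pos))
        if i < keys.size and int(keys[i]) == int(pos):
            return int(values[i])
        return None

    def bsb_to_tc(self, pos: int) -> int | None:
        return self._lookup(self.bsb_pos, self.tc_pos, int(pos))

    def tc_to_bsb(self, pos: int) -> int | None:
        return self._lookup(self.tc_pos, self.bsb_pos, int(pos))


@dataclass(frozen=True)
class ASEvent:
    """A typed, coordinate-anchored splicing difference between two chains.

    ``anchor`` is the type-specific identity coordinate tuple; events with the
    same (gene, type, anchor) are the same event regardless of which chain
    pair exposed them.
    """

    gene: str
    type: str
    anchor: tuple
    homoeolog: str = ""
    support: tuple = ()

    def __post_init__(self) -> None:
        if self.type not in AS_TYPES:
            raise InputShapeError(f"unknown AS event type {self.type!r}")

    @property
    def key(self) -> tuple:
        return (self.gene, self.type, self.anchor)


@dataclass(frozen=True)
class ReadAssignment:
    """Outcome of voting a short read's SNP alleles against the two parents."""

    read_id: str
    pair_id: str
    covered: int
    matches_bsb: int
    matches_tc: int
    call: str  # BSB | TC | ambiguous

    def __post_init__(self) -> None:
        if self.matches_bsb + self.matches_tc > self.covered:
            raise InputShapeError("allele matches exceed covered SNP count")


@dataclass(frozen=True)
class LongRead:
    """A long (full-length candidate) read: structural flags + exon chain."""

    read_id: str
    gene: str
    length: int
    has_5prime_primer: bool
    has_3prime_primer: bool
    has_polyA: bool
    chain: ExonChain
    snp_calls: tuple = ()  # ((genomic_pos, base), ...)


def as_events_equal(a: Iterable[ASEvent], b: Iterable[ASEvent]) -> bool:
    """Event-for-event equality on (gene, type, anchor) identity keys."""
    return {e.key for e in a} == {e.key for e in b}
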