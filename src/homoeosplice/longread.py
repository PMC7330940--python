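"""Long-read handling: full-length classification, subgenome assignment and
alternative-splicing event classification from exon chains.

The AS classifier compares every unordered pair of distinct exon chains of a
gene and emits typed, coordinate-anchored events:

``SE``
    an internal exon of one chain is absent from the other, and the other
    chain joins the two flanking splice sites directly (it has the intron
    spanning the skipped exon).
``RI``
    an intron of one chain lies inside a single exon of the other whose outer
    edges coincide with the outer edges of the two exons flanking the intron.
``A5SS`` / ``A3SS``
    two introns share one boundary and differ at the other, while the exon on
    the differing side keeps its outer boundary; whether the differing
    boundary is the donor (5') or acceptor (3') side depends on strand.
``MXE``
    two internal exons, each exclusive to one chain, disjoint in coordinates
    and flanked by the same pair of splice sites.
``AP``
    the chains have identical internal junctions and differ only at a
    transcript-terminal boundary (start of the first or end of the last exon).
``OTHER``
    the chains differ structurally but none of the named patterns applies.

Events are deduplicated by their ``(gene, type, anchor)`` identity key, so an
event supported by several chain pairs is counted once.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

from .types import (
    ASEvent,
    BSB,
    CoordMap,
    ExonChain,
    InputShapeError,
    LongRead,
    TC,
)

logger = logging.getLogger(__name__)

#: minimum read length (bp, strict) for a full-length call
FL_MIN_LENGTH = 300
#: minimum fraction of covered species-specific SNPs that must match one
#: parent for a long read to be assigned to it (inclusive)
ASSIGN_CONCORDANCE = 0.85


# ---------------------------------------------------------------------------
# full-length classification and subgenome assignment
# ---------------------------------------------------------------------------

def classify_full_length(read: LongRead, min_length: int = FL_MIN_LENGTH) -> bool:
    """A read is full-length iff it exceeds ``min_length`` (strict) and has a
    5' primer, a 3' primer and a poly(A) tail."""
    return (
        read.length > min_length
        and read.has_5prime_primer
        and read.has_3prime_primer
        and read.has_polyA
    )


def assign_long_read(
    snp_calls: Iterable[tuple[int, str]],
    snps: Mapping[int, tuple[frozenset, frozenset]],
    threshold: float = ASSIGN_CONCORDANCE,
) -> str:
    """Assign a long read to a subgenome by SNP-allele concordance.

    ``snps`` maps a genomic position to the (BSB, TC) parental allele sets.
    The read is assigned to a parent iff at least ``threshold`` (inclusive)
    of its covered species-specific SNP alleles match that parent; otherwise
    it is unassigned.
    """
    covered = 0
    m_bsb = 0
    m_tc = 0
    for pos, base in snp_calls:
        alleles = snps.get(int(pos))
        if alleles is None:
            continue
        covered += 1
        bsb_alleles, tc_alleles = alleles
        if base in bsb_alleles:
            m_bsb += 1
        elif base in tc_alleles:
            m_tc += 1
    if covered == 0:
        return "unassigned:no_snp"
    if m_bsb >= threshold * covered:
        return BSB
    if m_tc >= threshold * covered:
        return TC
    return "unassigned"


# ---------------------------------------------------------------------------
# pairwise event detection
# ---------------------------------------------------------------------------

def _pair_events(a: ExonChain, b: ExonChain) -> list[tuple[str, tuple]]:
    """Events distinguishing two chains, as (type, anchor) tuples.

    Symmetric in its arguments: every rule is evaluated in both directions
    and anchors never depend on argument order.
    """
    if a.exons == b.exons:
        return []
    events: list[tuple[str, tuple]] = []
    exons_a, exons_b = set(a.exons), set(b.exons)
    introns_a, introns_b = set(a.introns), set(b.introns)
    strand = a.strand

    # SE: skipped internal exon
    for x, other_introns, other_exons in (
        (a, introns_b, exons_b),
        (b, introns_a, exons_a),
    ):
        for i in range(1, len(x.exons) - 1):
            exon = x.exons[i]
            if exon in other_exons:
                continue
            spanning = (x.exons[i - 1][1], x.exons[i + 1][0])
            if spanning in other_introns:
                events.append(("SE", exon))

    # RI: retained intron
    for x, other_exons in ((a, exons_b), (b, exons_a)):
        for i, intron in enumerate(x.introns):
            merged = (x.exons[i][0], x.exons[i + 1][1])
            if merged in other_exons:
                events.append(("RI", intron))

    # MXE: mutually exclusive internal exons with shared flanking sites
    for i in range(1, len(a.exons) - 1):
        ea = a.exons[i]
        if ea in exons_b:
            continue
        for j in range(1, len(b.exons) - 1):
            eb = b.exons[j]
            if eb in exons_a:
                continue
            if not (ea[1] <= eb[0] or eb[1] <= ea[0]):
                continue  # overlapping: not mutually exclusive exons
            if (
                a.exons[i - 1][1] == b.exons[j - 1][1]
                and a.exons[i + 1][0] == b.exons[j + 1][0]
            ):
                events.append(("MXE", tuple(sorted((ea, eb)))))

    # A5SS / A3SS: introns sharing one boundary; the exon on the differing
    # side must keep its outer boundary (this excludes SE/RI patterns).
    for i, (s1, e1) in enumerate(a.introns):
        for j, (s2, e2) in enumerate(b.introns):
            if (s1, e1) == (s2, e2):
                continue
            if e1 == e2 and s1 != s2:
                # differing boundary on the genomic-left side
                if a.exons[i][0] == b.exons[j][0]:
                    kind = "A5SS" if strand == "+" else "A3SS"
                    events.append((kind, (tuple(sorted((s1, s2))), e1)))
            elif s1 == s2 and e1 != e2:
                # differing boundary on the genomic-right side
                if a.exons[i + 1][1] == b.exons[j + 1][1]:
                    kind = "A3SS" if strand == "+" else "A5SS"
                    events.append((kind, (s1, tuple(sorted((e1, e2))))))

    # AP: identical internal junctions, terminal boundary differences only
    if introns_a == introns_b:
        if a.exons[0][0] != b.exons[0][0]:
            events.append(
                ("AP", ("start", tuple(sorted((a.exons[0][0], b.exons[0][0])))))
            )
        if a.exons[-1][1] != b.exons[-1][1]:
            events.append(
                ("AP", ("end", tuple(sorted((a.exons[-1][1], b.exons[-1][1])))))
            )

    if not events:
        # catch-all: anchored on the symmetric difference of exon intervals
        diff = tuple(sorted(exons_a ^ exons_b))
        events.append(("OTHER", diff))
    return events


def classify_as_events(
    chains: Sequence[ExonChain], homoeolog: str = ""
) -> list[ASEvent]:
    """Classify AS events among the isoform chains of one gene.

    All unordered pairs of structurally distinct chains are compared and the
    resulting events deduplicated by (gene, type, anchor); each event records
    the ids of every chain pair supporting it.
    """
    if len(chains) < 2:
        return []
    gene = chains[0].gene
    for chain in chains:
        if chain.gene != gene:
            raise InputShapeError(
                f"chain {chain.chain_id or chain.exons} belongs to gene "
                f"{chain.gene!r}, expected {gene!r}"
            )
        if chain.strand != chains[0].strand:
            raise InputShapeError(f"inconsistent strand in chains of {gene}")
    support: dict[tuple, set] = defaultdict(set)
    for i in range(len(chains)):
        for j in range(i + 1, len(chains)):
            a, b = chains[i], chains[j]
            for etype, anchor in _pair_events(a, b):
                support[(etype, anchor)].update(
                    (a.chain_id or str(i), b.chain_id or str(j))
                )
    events = [
        ASEvent(
            gene=gene,
            type=etype,
            anchor=anchor,
            homoeolog=homoeolog,
            support=tuple(sorted(support[(etype, anchor)])),
        )
        for (etype, anchor) in support
    ]
    events.sort(key=lambda e: (e.type, repr(e.anchor)))
    return events


# ---------------------------------------------------------------------------
# cross-subgenome event matching and high-AS genes
# ---------------------------------------------------------------------------

def _map_anchor(anchor, mapper) -> tuple | None:
    """Map every integer coordinate in a (possibly nested) anchor tuple."""
    if isinstance(anchor, tuple):
        mapped = tuple(_map_anchor(part, mapper) for part in anchor)
        return None if any(part is None for part in mapped) else mapped
    if isinstance(anchor, (int,)):
        return mapper(anchor)
    return anchor  # side labels such as "start"/"end"


def shared_as_across_homoeologs(
    events_bsb: Iterable[ASEvent],
    events_tc: Iterable[ASEvent],
    coordmaps: Mapping[str, CoordMap],
    pair_of_gene: Mapping[str, str],
) -> list[tuple[ASEvent, ASEvent]]:
    """Match events between the two homoeologs of each ortholog pair.

    Two events match iff they have the same type and the BSB anchor maps
    exactly onto the TC anchor through the pair's coordinate map.
    ``pair_of_gene`` maps a gene id (either side) to its pair id.
    """
    tc_index: dict[tuple, ASEvent] = {}
    for ev in events_tc:
        pair = pair_of_gene.get(ev.gene)
        if pair is None:
            continue
        tc_index[(pair, ev.type, ev.anchor)] = ev
    matches = []
    for ev in events_bsb:
        pair = pair_of_gene.get(ev.gene)
        if pair is None or pair not in coordmaps:
            continue
        cmap = coordmaps[pair]
        mapped = _map_anchor(ev.anchor, cmap.bsb_to_tc)
        if mapped is None:
            logger.info("unmapped anchor for %s %s %r", ev.gene, ev.type, ev.anchor)
            continue
        hit = tc_index.get((pair, ev.type, mapped))
        if hit is not None:
            matches.append((ev, hit))
    return matches


def high_as_genes(events: Iterable[ASEvent], min_events: int = 5) -> list[str]:
    """Genes carrying at least ``min_events`` distinct AS events."""
    per_gene: dict[str, set] = defaultdict(set)
    for ev in events:
        per_gene[ev.gene].add(ev.key)
    return sorted(g for g, ks in per_gene.items() if len(ks) >= min_events)


def shared_high_as_genes(gene_lists: Sequence[Iterable[str]]) -> list[str]:
    """Genes that are high-AS in every provided list (e.g. all tissues)."""
    if not gene_lists:
        return []
    shared = set(gene_lists[0])
    for other in gene_lists[1:]:
        shared &= set(other)
    return sorted(shared)
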