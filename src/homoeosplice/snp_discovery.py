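"""Species-specific SNP discovery from parental pileups over a pairwise
coordinate map.

A species-specific SNP is an aligned, indel-free column at which the two
inbred parents show *disjoint* allele sets (homozygous or heterozygous) in
every biological replicate, with read coverage in all six parent-replicate
libraries.  Disjointness is what makes a column diagnostic of a hybrid
read's subgenome of origin: BSB={A,T} vs TC={G} qualifies, BSB={A,G} vs
TC={G} does not.
"""

from __future__ import annotations

import logging
from typing import Mapping

import pandas as pd

from .types import (
    BSB,
    TC,
    REPLICATES,
    CoordMap,
    InputShapeError,
    MappingError,
    SpeciesSNP,
)

logger = logging.getLogger(__name__)

#: minimum fraction of a column's reads required to admit a base into the
#: observed allele set (suppresses sequencing error)
MIN_MINOR_FRACTION = 0.2


def build_coordinate_map(
    pair_id: str, aligned_bsb: str, aligned_tc: str
) -> CoordMap:
    """Column-by-column coordinate map from a gapped pairwise alignment.

    Columns where either sequence is gapped are indel columns: the ungapped
    side's position is flagged and excluded from the mapping, so SNP calling
    can never land there.
    """
    if len(aligned_bsb) != len(aligned_tc):
        raise MappingError("aligned sequences differ in length")
    bsb_cols, tc_cols = [], []
    indel_bsb, indel_tc = [], []
    b = t = 0
    for cb, ct in zip(aligned_bsb, aligned_tc):
        if cb != "-" and ct != "-":
            bsb_cols.append(b)
            tc_cols.append(t)
            b += 1
            t += 1
        elif cb != "-":
            indel_bsb.append(b)
            b += 1
        elif ct != "-":
            indel_tc.append(t)
            t += 1
        # a double gap column carries no position on either side
    if not bsb_cols:
        raise MappingError(f"{pair_id}: alignment has no aligned columns")
    return CoordMap(pair_id, bsb_cols, tc_cols, indel_bsb, indel_tc)


def _allele_set(counts: Mapping[str, int], min_minor_frac: float) -> frozenset:
    total = sum(counts.values())
    if total == 0:
        return frozenset()
    return frozenset(
        base for base, c in counts.items() if c > 0 and c / total >= min_minor_frac
    )


def call_species_snps(
    coordmap: CoordMap,
    pileups: pd.DataFrame,
    min_minor_frac: float = MIN_MINOR_FRACTION,
    consistency: str = "strict",
) -> list[SpeciesSNP]:
    """Call species-specific SNPs for one ortholog pair.

    ``pileups`` rows carry ``parent`` (BSB/TC), ``replicate`` (1..3),
    ``pos`` (the parent's own gene coordinate) and A/C/G/T counts.  A column
    is emitted iff

    * it is an aligned, non-indel column of the coordinate map,
    * every one of the six parent-replicates has coverage >= 1,
    * the two parents' observed allele sets are disjoint, and
    * each parent's allele set is replicate-consistent (``strict``:
      identical in all three replicates; ``majority``: a base counts if
      admitted in at least two of three).
    """
    if consistency not in ("strict", "majority"):
        raise InputShapeError(f"unknown consistency mode {consistency!r}")
    reps = sorted(pileups["replicate"].unique())
    if list(reps) != list(REPLICATES):
        raise InputShapeError(
            f"expected replicates {list(REPLICATES)}, found {list(reps)}"
        )

    by_parent_pos: dict[tuple, dict[int, dict]] = {}
    for rec in pileups.itertuples():
        key = (rec.parent, int(rec.pos))
        by_parent_pos.setdefault(key, {})[int(rec.replicate)] = {
            "A": int(rec.A),
            "C": int(rec.C),
            "G": int(rec.G),
            "T": int(rec.T),
        }

    candidate_bsb = sorted(
        {pos for parent, pos in by_parent_pos if parent == BSB}
    )
    snps: list[SpeciesSNP] = []
    for bpos in candidate_bsb:
        tpos = coordmap.bsb_to_tc(bpos)
        if tpos is None or bpos in coordmap.indel_bsb or tpos in coordmap.indel_tc:
            continue
        per_parent_sets: dict[str, list[frozenset]] = {}
        per_parent_cov: dict[str, list[int]] = {}
        ok = True
        for parent, pos in ((BSB, bpos), (TC, tpos)):
            reps_counts = by_parent_pos.get((parent, pos))
            if reps_counts is None or set(reps_counts) != set(REPLICATES):
                ok = False
                break
            sets, covs = [], []
            for rep in REPLICATES:
                counts = reps_counts[rep]
                cov = sum(counts.values())
                if cov < 1:
                    ok = False
                    break
                sets.append(_allele_set(counts, min_minor_frac))
                covs.append(cov)
            if not ok:
                break
            per_parent_sets[parent] = sets
            per_parent_cov[parent] = covs
        if not ok:
            continue

        consolidated = {}
        for parent in (BSB, TC):
            sets = per_parent_sets[parent]
            if consistency == "strict":
                if not (sets[0] == sets[1] == sets[2]):
                    consolidated = None
                    break
                consolidated[parent] = sets[0]
            else:
                bases = set().union(*sets)
                consolidated[parent] = frozenset(
                    b for b in bases if sum(b in s for s in sets) >= 2
                )
                if not consolidated[parent]:
                    consolidated = None
                    break
        if consolidated is None:
            continue
        if consolidated[BSB] & consolidated[TC]:
            continue  # alleles intersect: not diagnostic of origin
        if not consolidated[BSB] or not consolidated[TC]:
            continue
        snps.append(
            SpeciesSNP(
                pair_id=coordmap.pair_id,
                bsb_pos=int(bpos),
                tc_pos=int(tpos),
                bsb_alleles=consolidated[BSB],
                tc_alleles=consolidated[TC],
                bsb_coverage=tuple(per_parent_cov[BSB]),
                tc_coverage=tuple(per_parent_cov[TC]),
            )
        )
    return snps


def snps_to_frame(snps: list[SpeciesSNP]) -> pd.DataFrame:
    """Tabular (VCF-like, 1-based positions) view of a SNP list."""
    rows = [
        {
            "pair_id": s.pair_id,
            "bsb_pos1": s.bsb_pos + 1,
            "tc_pos1": s.tc_pos + 1,
            "bsb_alleles": "".join(sorted(s.bsb_alleles)),
            "tc_alleles": "".join(sorted(s.tc_alleles)),
            "bsb_cov": ",".join(map(str, s.bsb_coverage)),
            "tc_cov": ",".join(map(str, s.tc_coverage)),
        }
        for s in snps
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "pair_id",
            "bsb_pos1",
            "tc_pos1",
            "bsb_alleles",
            "tc_alleles",
            "bsb_cov",
            "tc_cov",
        ],
    )
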