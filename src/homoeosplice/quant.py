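"""Subgenome partitioning of hybrid short reads and homoeolog counting.

Reads are voted to a subgenome by the parental alleles they carry at
species-specific SNPs (strict majority; ties and SNP-free reads stay
ambiguous).  Per-SNP read counts are consistency-filtered, outlier cells
are removed with a mean +/- 2SD rule, per-gene homoeolog counts are the
sums over the gene's surviving SNPs, and libraries are scaled to counts
per million (CPM) before expression filtering.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    BSB,
    TC,
    REPLICATES,
    IntegrityError,
    ReadAssignment,
    SpeciesSNP,
    StatisticsError,
)

logger = logging.getLogger(__name__)

OUTLIER_SD_FACTOR = 2.0
MIN_GENE_COUNT = 5
MITO_MATERNAL_FRACTION = 0.95

SNP_COUNT_COLUMNS = (
    "pair_id",
    "pos",
    "hybrid",
    "tissue",
    "replicate",
    "bsb_reads",
    "tc_reads",
)


def parse_calls(calls: str) -> list[tuple[int, str]]:
    """Parse a ``pos:base;pos:base`` call string."""
    if not calls:
        return []
    out = []
    for token in calls.split(";"):
        pos, base = token.split(":")
        out.append((int(pos), base))
    return out


def snp_lookup(snps: Iterable[SpeciesSNP]) -> dict[str, dict[int, tuple]]:
    """Per-pair mapping of SNP column -> (BSB alleles, TC alleles).

    Columns are keyed by the BSB-side coordinate, which is the shared column
    space the read tables call against.
    """
    lookup: dict[str, dict[int, tuple]] = {}
    for s in snps:
        lookup.setdefault(s.pair_id, {})[s.bsb_pos] = (s.bsb_alleles, s.tc_alleles)
    return lookup


def assign_short_read(
    read_snp_calls: Iterable[tuple[int, str]],
    snps: Mapping[int, tuple],
    read_id: str = "",
    pair_id: str = "",
) -> ReadAssignment:
    """Vote one read's SNP alleles against the two parents.

    The call is the parent matched by a strict majority of the covered SNP
    alleles; a read covering no SNP, a tie, or a majority of alleles
    matching neither parent leaves the read ambiguous.  A call at a position
    absent from the SNP table is a data-integrity error.
    """
    covered = 0
    m_bsb = 0
    m_tc = 0
    for pos, base in read_snp_calls:
        entry = snps.get(int(pos))
        if entry is None:
            raise IntegrityError(
                f"read {read_id or '<anonymous>'} calls position {pos} "
                f"absent from the SNP table of {pair_id or '<pair>'}"
            )
        covered += 1
        bsb_alleles, tc_alleles = entry
        if base in bsb_alleles:
            m_bsb += 1
        elif base in tc_alleles:
            m_tc += 1
    if m_bsb > covered / 2:
        call = BSB
    elif m_tc > covered / 2:
        call = TC
    else:
        call = "ambiguous"
    return ReadAssignment(read_id, pair_id, covered, m_bsb, m_tc, call)


def assign_reads_frame(
    reads: pd.DataFrame, lookup: Mapping[str, Mapping[int, tuple]]
) -> pd.DataFrame:
    """Assign every read in a short-read table; returns the table with
    ``covered``/``matches_bsb``/``matches_tc``/``call`` columns appended.

    Calls at SNP columns the table does not know (e.g. planted negatives
    that failed discovery) are ignored rather than counted for a parent,
    mirroring a mapping-file scan restricted to the validated SNP set.
    """
    covered = np.zeros(len(reads), dtype=np.int32)
    m_bsb = np.zeros(len(reads), dtype=np.int32)
    m_tc = np.zeros(len(reads), dtype=np.int32)
    calls_out = []
    pair_ids = reads["pair_id"].to_numpy()
    call_strings = reads["calls"].to_numpy()
    for i in range(len(reads)):
        table = lookup.get(pair_ids[i], {})
        c = b = t = 0
        for pos, base in parse_calls(call_strings[i]):
            entry = table.get(pos)
            if entry is None:
                continue
            c += 1
            if base in entry[0]:
                b += 1
            elif base in entry[1]:
                t += 1
        covered[i], m_bsb[i], m_tc[i] = c, b, t
        if b > c / 2:
            calls_out.append(BSB)
        elif t > c / 2:
            calls_out.append(TC)
        else:
            calls_out.append("ambiguous")
    out = reads.copy()
    out["covered"] = covered
    out["matches_bsb"] = m_bsb
    out["matches_tc"] = m_tc
    out["call"] = calls_out
    return out


def snp_allele_counts(
    reads: pd.DataFrame, lookup: Mapping[str, Mapping[int, tuple]]
) -> pd.DataFrame:
    """Per-SNP, per-replicate parental-allele read counts for one tissue.

    Each read contributes one count to a SNP's BSB (resp. TC) tally per
    covered SNP whose called base matches that parent's alleles.  SNPs with
    zero total reads in any replicate of the tissue (within a hybrid) are
    dropped, per the coverage-in-all-replicates rule.
    """
    if reads["tissue"].nunique() > 1:
        raise IntegrityError("snp_allele_counts expects reads from one tissue")
    acc: dict[tuple, list] = {}
    pair_ids = reads["pair_id"].to_numpy()
    hybrids = reads["hybrid"].to_numpy()
    tissues = reads["tissue"].to_numpy()
    replicates = reads["replicate"].to_numpy()
    call_strings = reads["calls"].to_numpy()
    for i in range(len(reads)):
        table = lookup.get(pair_ids[i], {})
        for pos, base in parse_calls(call_strings[i]):
            entry = table.get(pos)
            if entry is None:
                continue
            key = (pair_ids[i], pos, hybrids[i], tissues[i], int(replicates[i]))
            cell = acc.setdefault(key, [0, 0])
            if base in entry[0]:
                cell[0] += 1
            elif base in entry[1]:
                cell[1] += 1
    rows = [
        {
            "pair_id": k[0],
            "pos": k[1],
            "hybrid": k[2],
            "tissue": k[3],
            "replicate": k[4],
            "bsb_reads": v[0],
            "tc_reads": v[1],
        }
        for k, v in acc.items()
    ]
    df = pd.DataFrame(rows, columns=list(SNP_COUNT_COLUMNS))
    if df.empty:
        return df
    # a SNP must have >= 1 read in every replicate of each hybrid's tissue
    # contrast to be retained
    df["total"] = df["bsb_reads"] + df["tc_reads"]
    keep = []
    for (pair, pos, hybrid), sub in df.groupby(
        ["pair_id", "pos", "hybrid"], sort=False
    ):
        reps_present = set(sub.loc[sub["total"] >= 1, "replicate"])
        if reps_present == set(REPLICATES):
            keep.append((pair, pos, hybrid))
    keyframe = pd.DataFrame(keep, columns=["pair_id", "pos", "hybrid"])
    df = df.merge(keyframe, on=["pair_id", "pos", "hybrid"], how="inner")
    return df.drop(columns="total").sort_values(
        ["pair_id", "pos", "hybrid", "replicate"], ignore_index=True
    )


def filter_outlier_snps(
    snp_counts: pd.DataFrame,
    mode: str = "across_snps_within_gene",
    sd_factor: float = OUTLIER_SD_FACTOR,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop abnormal per-SNP read-count cells by a mean +/- 2SD rule.

    ``across_replicates`` applies the rule literally to each SNP's three
    replicate totals — provably vacuous, since with n values the largest
    attainable sample z-score is (n-1)/sqrt(n) (~1.155 for n=3), below 2.
    The default ``across_snps_within_gene`` compares each SNP's total
    against all SNP totals of the same gene in the same library, which can
    actually remove inflated cells.  Cells whose reference group has fewer
    than two values are retained with a warning.  Returns the filtered
    table and the dropped cells.
    """
    if mode not in ("across_replicates", "across_snps_within_gene"):
        raise ValueError(f"unknown outlier filter mode {mode!r}")
    if snp_counts.empty:
        return snp_counts.copy(), snp_counts.copy()
    df = snp_counts.copy()
    totals = (df["bsb_reads"] + df["tc_reads"]).to_numpy(dtype=float)
    df["_total"] = totals
    if mode == "across_replicates":
        group_cols = ["pair_id", "pos", "hybrid", "tissue"]
    else:
        group_cols = ["pair_id", "hybrid", "tissue", "replicate"]
    drop_mask = np.zeros(len(df), dtype=bool)
    for _, sub in df.groupby(group_cols, sort=False):
        values = sub["_total"].to_numpy()
        if len(values) < 2:
            logger.warning(
                "outlier filter: group %s has <2 values, cells retained",
                tuple(sub.iloc[0][group_cols]),
            )
            continue
        mean = values.mean()
        sd = values.std(ddof=1)
        if sd == 0:
            continue
        z = np.abs(values - mean) / sd
        drop_mask[sub.index.to_numpy()[z > sd_factor]] = True
    dropped = df.loc[drop_mask].drop(columns="_total").reset_index(drop=True)
    kept = df.loc[~drop_mask].drop(columns="_total").reset_index(drop=True)
    for rec in dropped.itertuples():
        logger.info(
            "dropped outlier SNP cell %s:%d %s/%s rep%d (reason=mean±2SD/%s)",
            rec.pair_id, rec.pos, rec.hybrid, rec.tissue, rec.replicate, mode,
        )
    return kept, dropped


def gene_homoeolog_counts(
    snp_counts: pd.DataFrame, pairs: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-gene homoeolog counts: sums over the gene's surviving SNPs.

    If ``pairs`` is given, genes with every SNP filtered away appear with
    (0, 0) counts and ``no_snp_data`` flagged.
    """
    if snp_counts.empty:
        grouped = pd.DataFrame(
            columns=["pair_id", "hybrid", "tissue", "replicate", "bsb_count", "tc_count"]
        )
    else:
        grouped = (
            snp_counts.groupby(
                ["pair_id", "hybrid", "tissue", "replicate"], sort=True, as_index=False
            )[["bsb_reads", "tc_reads"]]
            .sum()
            .rename(columns={"bsb_reads": "bsb_count", "tc_reads": "tc_count"})
        )
    grouped["no_snp_data"] = False
    if pairs is not None and not grouped.empty:
        libs = grouped[["hybrid", "tissue", "replicate"]].drop_duplicates()
        full = (
            pd.DataFrame({"pair_id": sorted(pairs)})
            .merge(libs, how="cross")
        )
        grouped = full.merge(
            grouped, on=["pair_id", "hybrid", "tissue", "replicate"], how="left"
        )
        missing = grouped["bsb_count"].isna()
        grouped.loc[missing, ["bsb_count", "tc_count"]] = 0
        grouped.loc[missing, "no_snp_data"] = True
        grouped["bsb_count"] = grouped["bsb_count"].astype(int)
        grouped["tc_count"] = grouped["tc_count"].astype(int)
        grouped["no_snp_data"] = grouped["no_snp_data"].astype(bool)
    return grouped.sort_values(
        ["pair_id", "hybrid", "tissue", "replicate"], ignore_index=True
    )


def normalize_and_filter(
    matrix: pd.DataFrame, min_count: int = MIN_GENE_COUNT
) -> tuple[pd.DataFrame, dict]:
    """Scale each library to counts per million and apply expression filters.

    A library is one (hybrid, tissue, replicate); its size is the total of
    all homoeolog counts it contains, so the CPM values of one library sum
    to 10^6 before any gene filtering.  For each contrast (homoeolog x
    tissue, between the two hybrids) a gene is retained iff its raw count
    is >= ``min_count`` in all three replicates of both hybrids.
    """
    df = matrix.copy()
    lib_sizes = (
        df.groupby(["hybrid", "tissue", "replicate"])[["bsb_count", "tc_count"]]
        .transform("sum")
        .sum(axis=1)
    )
    if (lib_sizes == 0).any():
        raise StatisticsError("zero-total library: cannot normalize to CPM")
    df["bsb_cpm"] = df["bsb_count"] / lib_sizes * 1e6
    df["tc_cpm"] = df["tc_count"] / lib_sizes * 1e6

    retained: dict[tuple, list] = {}
    for (tissue,), sub in df.groupby(["tissue"]):
        for homoeolog, col in ((BSB, "bsb_count"), (TC, "tc_count")):
            ok_genes = []
            for pair, gsub in sub.groupby("pair_id", sort=True):
                if len(gsub) < 2 * len(REPLICATES):
                    continue
                if (gsub[col] >= min_count).all():
                    ok_genes.append(pair)
            retained[(homoeolog, tissue)] = ok_genes
    return df, retained


def mito_origin_check(
    bsb_reads: int,
    tc_reads: int,
    threshold: float = MITO_MATERNAL_FRACTION,
) -> str:
    """Call the maternal mitogenome from mito-mapped read counts.

    The mitogenome holding at least ``threshold`` of the mitochondrial reads
    is called maternal; anything less decisive (including zero reads) is
    undetermined.
    """
    total = bsb_reads + tc_reads
    if total == 0:
        return "undetermined"
    if bsb_reads / total >= threshold:
        return BSB
    if tc_reads / total >= threshold:
        return TC
    return "undetermined"
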