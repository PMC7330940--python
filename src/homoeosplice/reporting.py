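"""Publication-shaped summaries and the end-to-end pipeline runner.

The summary builders reproduce the arithmetic of the study-style tables:
an AS-event summary (per event type x homoeolog-column counts, percentages
and gene counts, with a Total row), a full-length read summary (counts with
percent of consensus reads), and the homoeolog AS-share split.  Percentages
are printed with banker's (half-even) rounding to two decimals and every
rendered table is self-audited against its recomputed totals.

``run_pipeline`` chains the stages (simulate -> orthologs -> snps ->
quantify -> de -> as -> report) over an output directory; each stage loads
its inputs from the previous stage's files when not already in memory and
raises :class:`DependencyError` naming the missing stage otherwise.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import defaultdict
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import de as de_mod
from . import longread, orthology, quant, snp_discovery, tables
from .synthetic import SimBundle, SimConfig, generate_cohort
from .types import (
    BSB,
    TC,
    HYBRIDS,
    TISSUES,
    ASEvent,
    DependencyError,
    ExonChain,
    InputShapeError,
)

logger = logging.getLogger(__name__)

AS_TABLE_ORDER = ("A3SS", "A5SS", "AP", "SE", "RI", "OTHER")
AS_TYPE_LABELS = {
    "A3SS": "Alternative 3' splice site",
    "A5SS": "Alternative 5' splice site",
    "AP": "Alternative site",
    "SE": "Exon skipping",
    "RI": "Retained introns",
    "OTHER": "Other",
}
STAGES = ("simulate", "orthologs", "snps", "quantify", "de", "as", "report")


def round_half_even(value: float, ndigits: int = 2) -> float:
    """Banker's rounding, used everywhere a percentage is printed."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_EVEN))


def percent(count: float, total: float, ndigits: int = 2) -> float:
    if total == 0:
        return 0.0
    return round_half_even(100.0 * count / total, ndigits)


# ---------------------------------------------------------------------------
# summary tables
# ---------------------------------------------------------------------------

def as_summary_table(
    columns: Mapping[str, Mapping[str, int]],
    gene_counts: Mapping[str, Mapping[str, int]] | None = None,
) -> pd.DataFrame:
    """AS-event summary in the shape of the study's per-homoeolog table.

    ``columns`` maps a column label (homoeolog x hybrid) to per-type event
    counts; ``gene_counts`` optionally supplies per-type gene counts.  Rows
    follow the fixed type order plus a Total row; percentages are of the
    column total.  Degenerate (all-zero) columns are flagged and report
    0.00 percentages.
    """
    rows = []
    for etype in AS_TABLE_ORDER + ("Total",):
        row: dict = {"as_type": etype, "label": AS_TYPE_LABELS.get(etype, "Total")}
        for col, counts in columns.items():
            for c in counts.values():
                if c < 0:
                    raise InputShapeError(f"negative event count in column {col}")
            total = sum(int(counts.get(t, 0)) for t in AS_TABLE_ORDER)
            if etype == "Total":
                n = total
                pct = 100.0 if total else 0.0
            else:
                n = int(counts.get(etype, 0))
                pct = percent(n, total)
            row[f"{col}_events"] = n
            row[f"{col}_pct"] = round_half_even(pct)
            if gene_counts is not None:
                gc = gene_counts.get(col, {})
                row[f"{col}_genes"] = (
                    int(gc.get(etype, 0)) if etype != "Total" else sum(
                        int(gc.get(t, 0)) for t in AS_TABLE_ORDER
                    )
                )
            if total == 0:
                row[f"{col}_degenerate"] = True
        rows.append(row)
    df = pd.DataFrame(rows)
    _audit_as_table(df, columns)
    return df


def _audit_as_table(df: pd.DataFrame, columns: Mapping) -> None:
    """Self-audit: Total rows equal recomputed sums, percentages sum to 100."""
    body = df[df["as_type"] != "Total"]
    total_row = df[df["as_type"] == "Total"].iloc[0]
    for col in columns:
        s = int(body[f"{col}_events"].sum())
        if s != int(total_row[f"{col}_events"]):
            raise AssertionError(f"AS summary total mismatch in column {col}")
        if s > 0:
            # six rows each rounded to 2 decimals: worst-case drift 0.03
            psum = float(body[f"{col}_pct"].sum())
            if abs(psum - 100.0) > 0.03 + 1e-9:
                raise AssertionError(
                    f"AS summary percentages of {col} sum to {psum}"
                )


def fl_summary_table(
    consensus: Mapping[str, int],
    five_prime: Mapping[str, int],
    three_prime: Mapping[str, int],
    full_length: Mapping[str, int],
) -> pd.DataFrame:
    """Full-length read summary: counts with percent of consensus reads."""
    rows = []
    for metric, counts in (
        ("consensus_reads", consensus),
        ("five_prime_reads", five_prime),
        ("three_prime_reads", three_prime),
        ("full_length_reads", full_length),
    ):
        row: dict = {"metric": metric}
        for col, n in counts.items():
            if n < 0:
                raise InputShapeError("counts must be non-negative")
            row[f"{col}_count"] = int(n)
            if metric != "consensus_reads":
                row[f"{col}_pct"] = percent(n, consensus[col])
        rows.append(row)
    return pd.DataFrame(rows)


def homoeolog_as_share(tc_events: int, bsb_events: int) -> tuple[float, float]:
    """Split of AS events between the TC and BSB homoeologs, as percents."""
    if tc_events < 0 or bsb_events < 0:
        raise InputShapeError("event counts must be non-negative")
    total = tc_events + bsb_events
    if total == 0:
        raise InputShapeError("homoeolog AS share undefined when both counts are 0")
    return (percent(tc_events, total), percent(bsb_events, total))


def render_aligned(df: pd.DataFrame) -> str:
    """Fixed-width text rendering of a summary table."""
    cols = list(df.columns)
    widths = {
        c: max(len(str(c)), *(len(str(v)) for v in df[c])) for c in cols
    }
    lines = ["  ".join(str(c).ljust(widths[c]) for c in cols)]
    for _, row in df.iterrows():
        lines.append("  ".join(str(row[c]).ljust(widths[c]) for c in cols))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _load_config(config) -> SimConfig:
    if isinstance(config, SimConfig):
        return config
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    config = dict(config)
    for key in ("exons_per_gene", "exon_len", "intron_len"):
        if key in config and isinstance(config[key], list):
            config[key] = tuple(config[key])
    return SimConfig(**config)


def _meta(config: SimConfig) -> dict:
    mapping = dataclasses.asdict(config)
    return {"seed": config.seed, "config_sha256": tables.config_hash(mapping)}


class Pipeline:
    """Stage-wise pipeline over one output directory.

    Stages run in dependency order; a stage finding neither in-memory state
    nor the predecessor's output files raises :class:`DependencyError`.
    """

    def __init__(self, config, outdir: str | Path):
        self.config = _load_config(config)
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.meta = _meta(self.config)
        self.state: dict = {}

    # -- helpers ---------------------------------------------------------
    def _path(self, name: str) -> Path:
        return self.outdir / name

    def _require(self, key: str, filename: str, loader, stage: str):
        if key in self.state:
            return self.state[key]
        path = self._path(filename)
        if not path.exists():
            raise DependencyError(
                f"stage '{stage}' requires output '{filename}' — run the "
                f"producing stage first"
            )
        value = loader(path)
        self.state[key] = value
        return value

    # -- stages ----------------------------------------------------------
    def simulate(self) -> SimBundle:
        bundle = generate_cohort(self.config)
        self.state["bundle"] = bundle
        m = self.meta
        tables.write_gtf(bundle.models_bsb.values(), self._path("genes_bsb.gtf"), m)
        tables.write_gtf(bundle.models_tc.values(), self._path("genes_tc.gtf"), m)
        tables.write_fasta(bundle.sequences, self._path("genes.fasta"))
        aln = pd.DataFrame(
            [
                {"pair_id": p, "aligned_bsb": a, "aligned_tc": b}
                for p, (a, b) in sorted(bundle.alignments.items())
            ]
        )
        tables.write_tsv(aln, self._path("alignments.tsv"), m)
        tables.write_tsv(bundle.pileups, self._path("pileups.tsv"), m)
        tables.write_tsv(bundle.short_reads, self._path("reads_short.tsv"), m)
        tables.write_tsv(bundle.long_reads, self._path("reads_long.tsv"), m)
        tables.write_tsv(bundle.truth.snps, self._path("truth_snps.tsv"), m)
        mito = pd.DataFrame(
            [
                {"hybrid": h, "bsb_mito_reads": c[0], "tc_mito_reads": c[1],
                 "true_maternal": bundle.truth.maternal[h]}
                for h, c in sorted(bundle.mito_counts.items())
            ]
        )
        tables.write_tsv(mito, self._path("mito_counts.tsv"), m)
        with open(self._path("config.yaml"), "w") as fh:
            yaml.safe_dump(
                {k: tables._plain(v) for k, v in dataclasses.asdict(self.config).items()},
                fh, sort_keys=True,
            )
        return bundle

    def orthologs(self):
        bundle = self.state.get("bundle")
        if bundle is None:
            raise DependencyError("stage 'orthologs' requires the simulate stage")
        tx_seqs_b, tx_seqs_t = {}, {}
        for gid, model in bundle.models_bsb.items():
            seq = bundle.sequences[gid]
            tx_seqs_b[gid] = "".join(seq[s:e] for s, e in model.exons)[:600]
        for gid, model in bundle.models_tc.items():
            seq = bundle.sequences[gid]
            tx_seqs_t[gid] = "".join(seq[s:e] for s, e in model.exons)[:600]
        scores = orthology.kmer_containment_scores(tx_seqs_b, tx_seqs_t)
        pairs = orthology.reciprocal_best_hits(scores)
        models = {**bundle.models_bsb, **bundle.models_tc}
        stats = orthology.structure_stats(pairs, models)
        self.state["rbh_pairs"] = pairs
        self.state["structure_stats"] = stats
        tables.write_tsv(
            pd.DataFrame(
                [
                    {"bsb_gene": p.bsb_gene, "tc_gene": p.tc_gene,
                     "score": p.score, "evalue": p.evalue_like}
                    for p in pairs
                ]
            ),
            self._path("orthologs.tsv"),
            self.meta,
        )
        flat = []
        for key, value in stats.items():
            if isinstance(value, dict):
                for sub, v in value.items():
                    flat.append({"statistic": f"{key}_{sub}", "value": v})
            else:
                flat.append({"statistic": key, "value": value})
        tables.write_tsv(pd.DataFrame(flat), self._path("structure_stats.tsv"), self.meta)
        return pairs, stats

    def snps(self):
        bundle = self.state.get("bundle")
        if bundle is not None:
            alignments = bundle.alignments
            pileups = bundle.pileups
        else:
            aln_df = self._require(
                "alignments_df", "alignments.tsv", tables.read_tsv, "snps"
            )
            alignments = {
                r.pair_id: (r.aligned_bsb, r.aligned_tc) for r in aln_df.itertuples()
            }
            pileups = self._require("pileups", "pileups.tsv", tables.read_tsv, "snps")
        maps = {
            pair: snp_discovery.build_coordinate_map(pair, a, b)
            for pair, (a, b) in alignments.items()
        }
        snps = []
        for pair, sub in pileups.groupby("pair_id", sort=True):
            if pair in maps:
                snps.extend(snp_discovery.call_species_snps(maps[pair], sub))
        self.state["coord_maps"] = maps
        self.state["snps"] = snps
        tables.write_tsv(
            snp_discovery.snps_to_frame(snps), self._path("snps.tsv"), self.meta
        )
        return snps

    def quantify(self):
        bundle = self.state.get("bundle")
        if bundle is not None:
            reads = bundle.short_reads
        else:
            reads = self._require(
                "short_reads", "reads_short.tsv", tables.read_tsv, "quantify"
            )
            reads = reads.fillna({"calls": ""})
        snps = self.state.get("snps")
        if snps is None:
            df = self._require("snps_df", "snps.tsv", tables.read_tsv, "quantify")
            snps = tables.snps_from_frame(df)
            self.state["snps"] = snps
        lookup = quant.snp_lookup(snps)
        per_tissue = []
        for tissue in TISSUES:
            sub = reads[reads["tissue"] == tissue]
            if len(sub):
                per_tissue.append(quant.snp_allele_counts(sub, lookup))
        snp_counts = (
            pd.concat(per_tissue, ignore_index=True)
            if per_tissue
            else pd.DataFrame(columns=list(quant.SNP_COUNT_COLUMNS))
        )
        filtered, dropped = quant.filter_outlier_snps(snp_counts)
        pair_ids = sorted({s.pair_id for s in snps})
        matrix = quant.gene_homoeolog_counts(filtered, pairs=pair_ids)
        norm, retained = quant.normalize_and_filter(matrix)
        self.state["snp_counts"] = filtered
        self.state["matrix"] = norm
        self.state["retained"] = retained
        m = self.meta
        tables.write_tsv(filtered, self._path("snp_counts.tsv"), m)
        tables.write_tsv(dropped, self._path("snp_counts_dropped.tsv"), m)
        tables.write_tsv(norm, self._path("gene_counts.tsv"), m)
        if bundle is not None:
            mito_rows = [
                {
                    "hybrid": h,
                    "bsb_mito_reads": c[0],
                    "tc_mito_reads": c[1],
                    "maternal_call": quant.mito_origin_check(c[0], c[1]),
                }
                for h, c in sorted(bundle.mito_counts.items())
            ]
            tables.write_tsv(
                pd.DataFrame(mito_rows), self._path("mito_origin.tsv"), m
            )
        return norm, retained

    def de(self):
        matrix = self.state.get("matrix")
        retained = self.state.get("retained")
        if matrix is None:
            matrix = self._require(
                "matrix", "gene_counts.tsv", tables.read_tsv, "de"
            )
            _, retained = quant.normalize_and_filter(
                matrix.drop(columns=[c for c in ("bsb_cpm", "tc_cpm") if c in matrix]),
            )
        results = []
        for tissue in TISSUES:
            for homoeolog in (BSB, TC):
                genes = retained.get((homoeolog, tissue), [])
                if not genes:
                    continue
                results.append(
                    de_mod.differential_expression(matrix, homoeolog, tissue, genes)
                )
        de_table = (
            pd.concat(results, ignore_index=True)
            if results
            else pd.DataFrame()
        )
        self.state["de_table"] = de_table
        tables.write_tsv(de_table, self._path("de.tsv"), self.meta)
        summaries = []
        for tissue in TISSUES:
            sub_b = de_table[
                (de_table["tissue"] == tissue) & (de_table["homoeolog"] == BSB)
            ] if len(de_table) else pd.DataFrame(columns=["pair_id", "deg", "direction"])
            sub_t = de_table[
                (de_table["tissue"] == tissue) & (de_table["homoeolog"] == TC)
            ] if len(de_table) else pd.DataFrame(columns=["pair_id", "deg", "direction"])
            if len(sub_b) or len(sub_t):
                venn = de_mod.shared_deg_summary(sub_b, sub_t)
                venn["tissue"] = tissue
                summaries.append(venn)
        tables.write_tsv(
            pd.DataFrame(summaries), self._path("de_summary.tsv"), self.meta
        )
        return de_table

    def as_stage(self):
        bundle = self.state.get("bundle")
        if bundle is not None:
            lr = bundle.long_reads
        else:
            lr = self._require("long_reads", "reads_long.tsv", tables.read_tsv, "as")
            lr = lr.fillna({"calls": ""})
        snps = self.state.get("snps")
        if snps is None:
            df = self._require("snps_df", "snps.tsv", tables.read_tsv, "as")
            snps = tables.snps_from_frame(df)
        lookup = quant.snp_lookup(snps)

        fl = np.array(
            [
                row.length > longread.FL_MIN_LENGTH
                and row.has_5prime_primer
                and row.has_3prime_primer
                and row.has_polyA
                for row in lr.itertuples()
            ],
            dtype=bool,
        )
        assigned = [
            longread.assign_long_read(
                quant.parse_calls(row.calls), lookup.get(row.pair_id, {})
            )
            for row in lr.itertuples()
        ]
        lr = lr.assign(full_length=fl, assigned=assigned)
        self.state["long_reads_classified"] = lr

        # chains of full-length reads whose SNP assignment confirms the
        # subgenome of the gene they map to
        subgenome = np.where(lr["gene"].str.startswith(TC), TC, BSB)
        usable = lr[(lr["full_length"]) & (lr["assigned"] == subgenome)]
        events_by_col: dict[tuple, list[ASEvent]] = defaultdict(list)
        for (hybrid, gene), sub in usable.groupby(["hybrid", "gene"], sort=True):
            homoeolog = TC if gene.startswith(TC) else BSB
            uniq: dict[tuple, ExonChain] = {}
            for row in sub.itertuples():
                exons = tables.exons_from_str(row.exons)
                uniq.setdefault(exons, ExonChain(gene, row.strand, exons, row.chain_id))
            chains = list(uniq.values())
            events = longread.classify_as_events(chains, homoeolog)
            events_by_col[(hybrid, homoeolog)].extend(events)
        self.state["as_events"] = events_by_col

        rows = []
        for (hybrid, homoeolog), events in sorted(events_by_col.items()):
            for ev in events:
                rows.append(
                    {
                        "hybrid": hybrid,
                        "homoeolog": homoeolog,
                        "gene": ev.gene,
                        "as_type": ev.type,
                        "anchor": repr(ev.anchor),
                        "support": ",".join(ev.support),
                    }
                )
        events_df = pd.DataFrame(
            rows, columns=["hybrid", "homoeolog", "gene", "as_type", "anchor", "support"]
        )
        tables.write_tsv(events_df, self._path("as_events.tsv"), self.meta)
        all_events = [ev for evs in events_by_col.values() for ev in evs]
        tables.write_events_bed(all_events, self._path("as_events.bed"), self.meta)

        maps = self.state.get("coord_maps")
        if maps is None and self._path("alignments.tsv").exists():
            aln_df = tables.read_tsv(self._path("alignments.tsv"))
            maps = {
                r.pair_id: snp_discovery.build_coordinate_map(
                    r.pair_id, r.aligned_bsb, r.aligned_tc
                )
                for r in aln_df.itertuples()
            }
        # gene -> pair mapping: pair ids encode the gene index on both sides
        pair_of_gene = {}
        for s in snps:
            idx = s.pair_id.replace("pair", "")
            pair_of_gene[f"BSB_g{idx}"] = s.pair_id
            pair_of_gene[f"TC_g{idx}"] = s.pair_id
        shared_rows = []
        if maps is not None:
            for hybrid in HYBRIDS:
                matches = longread.shared_as_across_homoeologs(
                    events_by_col.get((hybrid, BSB), []),
                    events_by_col.get((hybrid, TC), []),
                    maps,
                    pair_of_gene,
                )
                for ev_b, ev_t in matches:
                    shared_rows.append(
                        {
                            "hybrid": hybrid,
                            "bsb_gene": ev_b.gene,
                            "tc_gene": ev_t.gene,
                            "as_type": ev_b.type,
                            "anchor": repr(ev_b.anchor),
                        }
                    )
        tables.write_tsv(
            pd.DataFrame(
                shared_rows,
                columns=["hybrid", "bsb_gene", "tc_gene", "as_type", "anchor"],
            ),
            self._path("shared_as.tsv"),
            self.meta,
        )
        high_rows = []
        for (hybrid, homoeolog), events in sorted(events_by_col.items()):
            for gene in longread.high_as_genes(events):
                high_rows.append(
                    {"hybrid": hybrid, "homoeolog": homoeolog, "gene": gene}
                )
        tables.write_tsv(
            pd.DataFrame(high_rows, columns=["hybrid", "homoeolog", "gene"]),
            self._path("high_as.tsv"),
            self.meta,
        )
        return events_by_col

    def report(self):
        lr = self.state.get("long_reads_classified")
        events_by_col = self.state.get("as_events")
        if lr is None or events_by_col is None:
            raise DependencyError(
                "stage 'report' requires the long-read AS stage outputs"
            )
        consensus, five, three, flc = {}, {}, {}, {}
        for hybrid, sub in lr.groupby("hybrid"):
            consensus[hybrid] = len(sub)
            five[hybrid] = int(sub["has_5prime_primer"].sum())
            three[hybrid] = int(sub["has_3prime_primer"].sum())
            flc[hybrid] = int(sub["full_length"].sum())
        fl_table = fl_summary_table(consensus, five, three, flc)
        tables.write_tsv(fl_table, self._path("fl_summary.tsv"), self.meta)

        columns, gene_counts = {}, {}
        for (hybrid, homoeolog), events in sorted(events_by_col.items()):
            label = f"{homoeolog}_{hybrid}"
            counts: dict[str, int] = defaultdict(int)
            genes: dict[str, set] = defaultdict(set)
            for ev in events:
                # the summary table has no MXE row; MXE events are tallied
                # under Other, as in the study's table layout
                etype = ev.type if ev.type in AS_TABLE_ORDER else "OTHER"
                counts[etype] += 1
                genes[etype].add(ev.gene)
            columns[label] = dict(counts)
            gene_counts[label] = {t: len(g) for t, g in genes.items()}
        as_table = as_summary_table(columns, gene_counts)
        tables.write_tsv(as_table, self._path("as_summary.tsv"), self.meta)

        share_rows = []
        for hybrid in HYBRIDS:
            n_tc = len(events_by_col.get((hybrid, TC), []))
            n_bsb = len(events_by_col.get((hybrid, BSB), []))
            if n_tc + n_bsb:
                pct_tc, pct_bsb = homoeolog_as_share(n_tc, n_bsb)
                share_rows.append(
                    {
                        "hybrid": hybrid,
                        "tc_events": n_tc,
                        "bsb_events": n_bsb,
                        "tc_pct": pct_tc,
                        "bsb_pct": pct_bsb,
                    }
                )
        tables.write_tsv(
            pd.DataFrame(share_rows), self._path("as_share.tsv"), self.meta
        )

        text = [
            "Full-length read summary",
            render_aligned(fl_table),
            "AS event summary",
            render_aligned(as_table),
        ]
        bundle = self.state.get("bundle")
        if bundle is not None:
            recovery = truth_recovery_report(bundle, self.state)
            tables.write_tsv(
                pd.DataFrame(
                    [{"metric": k, "value": v} for k, v in recovery.items()]
                ),
                self._path("truth_recovery.tsv"),
                self.meta,
            )
            text.append("Truth recovery")
            text.extend(f"  {k} = {v}" for k, v in recovery.items())
        self._path("summary.txt").write_text("\n".join(text) + "\n")
        return fl_table, as_table

    def run(self, stages: Sequence[str] | None = None) -> dict:
        stages = list(stages) if stages is not None else list(STAGES)
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise InputShapeError(f"unknown stages: {sorted(unknown)}")
        for stage in STAGES:
            if stage not in stages:
                continue
            logger.info("running stage %s", stage)
            getattr(self, stage if stage != "as" else "as_stage")()
        return self.state


def truth_recovery_report(bundle: SimBundle, state: Mapping) -> dict:
    """How well each stage recovered the planted truth (end-to-end audit)."""
    out: dict = {}
    truth = bundle.truth
    snps = state.get("snps")
    if snps is not None:
        called = {(s.pair_id, s.bsb_pos) for s in snps}
        planted = {
            (r.pair_id, int(r.bsb_pos)) for r in truth.snps.itertuples()
        }
        out["snp_recall"] = (
            len(called & planted) / len(planted) if planted else float("nan")
        )
        out["snp_precision"] = (
            len(called & planted) / len(called) if called else float("nan")
        )
    events_by_col = state.get("as_events")
    if events_by_col is not None:
        planted_keys = {
            ev.key for evs in truth.as_events.values() for ev in evs
        }
        found_keys = set()
        for (hybrid, _), evs in events_by_col.items():
            found_keys |= {ev.key for ev in evs}
        named = {k for k in found_keys if k[1] != "OTHER"}
        out["as_event_recall"] = (
            len(planted_keys & found_keys) / len(planted_keys)
            if planted_keys
            else float("nan")
        )
        out["as_event_precision"] = (
            len(planted_keys & named) / len(named) if named else float("nan")
        )
    de_table = state.get("de_table")
    if de_table is not None and len(de_table):
        degs = set(de_table.loc[de_table["deg"], "pair_id"])
        out["de_recall"] = (
            len(degs & set(truth.de_genes)) / len(truth.de_genes)
            if truth.de_genes
            else float("nan")
        )
    for hybrid, (b_count, t_count) in sorted(bundle.mito_counts.items()):
        call = quant.mito_origin_check(b_count, t_count)
        out[f"mito_call_correct_{hybrid}"] = call == truth.maternal[hybrid]
    return out


def run_pipeline(config, outdir, stages: Sequence[str] | None = None) -> dict:
    """Run the pipeline over ``outdir``; returns the in-memory stage state."""
    return Pipeline(config, outdir).run(stages)
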