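"""Synthetic reciprocal-cross cohort generator with full ground truth.

The generator emulates the study design this pipeline targets: two diverged
inbred parental species (BSB and TC) with orthologous gene pairs, fixed
inter-species SNPs, two reciprocal-cross hybrids (TBF3: TC mother; BTF3: BSB
mother) sampled in three tissues with three biological replicates each, and
a pooled long-read library per hybrid carrying planted isoforms of every
named AS event class.

Reads are emitted as already-aligned records (gene, transcript offsets, base
calls at polymorphic columns); no read aligner is modelled — the bespoke
computation this package implements starts downstream of alignment.

Coordinate systems: per-gene genomic 0-based half-open positions.  Because
the two parental gene copies of a pair are simulated as substitution-diverged
(with an optional TC-private terminal exon), the pairwise alignment is the
identity on the shared gene body, with the TC-private tail as an indel block.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    AS_TYPES,
    BASES,
    BSB,
    TC,
    HYBRIDS,
    NAMED_AS_TYPES,
    REPLICATES,
    TISSUES,
    ASEvent,
    CapabilityError,
    ConfigError,
    ExonChain,
    GeneModel,
)

# fixed structural offsets used when planting isoform variants (bp)
ALT_SITE_DELTA = 15
AP_DELTA = 20
MXE_ALT_LEN = 40
MXE_ALT_GAP = 10

_SHORT_READ_COLUMNS = (
    "read_id",
    "pair_id",
    "hybrid",
    "tissue",
    "replicate",
    "start",
    "end",
    "true_origin",
    "calls",
)


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the simulated study; the defaults are the study design.

    Rates are probabilities in [0, 1]; ranges are inclusive (lo, hi) bp or
    counts; ``depth`` is the mean short-read count per gene per replicate
    library; ``seed`` fixes every downstream draw.
    """

    n_genes: int = 200
    exons_per_gene: tuple[int, int] = (6, 12)
    exon_len: tuple[int, int] = (80, 300)
    intron_len: tuple[int, int] = (60, 400)
    snp_rate: float = 0.02
    depth: float = 100.0
    bias_frac: float = 0.3
    bias_log2: float = 1.0
    de_frac: float = 0.1
    de_log2: float = 2.0
    as_events_per_gene: Mapping[str, int] = field(
        default_factory=lambda: {t: 1 for t in NAMED_AS_TYPES}
    )
    error_rate: float = 0.002
    outlier_snp_rate: float = 0.02
    outlier_inflation: float = 10.0
    seed: int = 0
    # secondary structure of the design
    read_length: int = 100
    long_reads_per_chain: int = 2
    parent_depth: float = 30.0
    het_snp_frac: float = 0.1
    shared_as_frac: float = 0.5
    extra_exon_frac: float = 0.25
    fl_flag_rate: float = 0.95
    mito_reads: int = 1000
    mito_purity: float = 0.995

    def __post_init__(self) -> None:
        for name in (
            "snp_rate",
            "bias_frac",
            "de_frac",
            "error_rate",
            "outlier_snp_rate",
            "het_snp_frac",
            "shared_as_frac",
            "extra_exon_frac",
            "fl_flag_rate",
            "mito_purity",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        for name in ("exons_per_gene", "exon_len", "intron_len"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigError(f"{name} range ({lo}, {hi}) is empty or invalid")
        if self.exons_per_gene[0] < 1:
            raise ConfigError("exons_per_gene must allow at least one exon")
        for name in ("n_genes", "read_length", "long_reads_per_chain", "mito_reads"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive integer")
        for name in ("depth", "parent_depth", "outlier_inflation"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for etype in self.as_events_per_gene:
            if etype not in NAMED_AS_TYPES:
                raise ConfigError(f"as_events_per_gene has unknown type {etype!r}")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError("seed must be an integer")


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort; every stage can be audited here."""

    ortholog_pairs: list = field(default_factory=list)  # (pair_id, bsb, tc)
    snps: pd.DataFrame | None = None
    negative_columns: pd.DataFrame | None = None
    gene_bias_log2: dict = field(default_factory=dict)  # (pair_id, tissue) -> b
    de_genes: dict = field(default_factory=dict)  # pair_id -> +1 / -1
    chains: dict = field(default_factory=dict)  # gene_id -> [ExonChain]
    as_events: dict = field(default_factory=dict)  # gene_id -> [ASEvent]
    shared_as_pairs: set = field(default_factory=set)
    outlier_cells: list = field(default_factory=list)
    long_read_fl: dict = field(default_factory=dict)  # read_id -> bool
    long_read_origin: dict = field(default_factory=dict)  # read_id -> BSB|TC
    maternal: dict = field(default_factory=lambda: {"TBF3": TC, "BTF3": BSB})


@dataclass
class SimBundle:
    """Everything a run of the pipeline consumes, plus the truth tables."""

    config: SimConfig
    truth: SimTruth
    models_bsb: dict
    models_tc: dict
    sequences: dict  # gene_id -> genomic sequence (str)
    alignments: dict  # pair_id -> (gapped BSB, gapped TC) genomic alignment
    pileups: pd.DataFrame | None = None
    short_reads: pd.DataFrame | None = None
    long_reads: pd.DataFrame | None = None
    mito_counts: dict = field(default_factory=dict)

    @property
    def pair_ids(self) -> list:
        return [p for p, _, _ in self.truth.ortholog_pairs]


# ---------------------------------------------------------------------------
# isoform planting
# ---------------------------------------------------------------------------

_SLOT_SPACING = 3  # internal-exon slots this far apart never interact


def _slots(model: GeneModel) -> list[int]:
    return list(range(1, model.exon_count - 1, _SLOT_SPACING))


def plant_as_isoforms(
    model: GeneModel, spec: Mapping[str, int]
) -> tuple[list[ExonChain], list[ASEvent]]:
    """Derive isoform chains realizing the requested AS events.

    Each requested event yields one variant chain differing from the
    reference chain by exactly that event; loci are chosen on well-separated
    internal exons so that events never interact.  Raises
    :class:`CapabilityError` when the gene cannot host the request (too few
    exons, introns too short, more than two terminal AP events).
    """
    counts = {t: int(c) for t, c in spec.items() if int(c) != 0}
    for etype, c in counts.items():
        if etype not in NAMED_AS_TYPES:
            raise CapabilityError(f"unknown AS event type {etype!r}")
        if c < 0:
            raise CapabilityError(f"negative count for {etype}")
    ref = model.chain(f"{model.gene_id}.ref")
    requested = [t for t in NAMED_AS_TYPES for _ in range(counts.get(t, 0))]
    if not requested:
        return [ref], []

    slot_types = ("SE", "RI", "A5SS", "A3SS", "MXE")
    n_slot_events = sum(1 for t in requested if t in slot_types)
    slots = _slots(model)
    if counts.get("AP", 0) > 2:
        raise CapabilityError("at most two AP events (one per transcript end)")
    if (counts.get("SE", 0) or counts.get("MXE", 0)) and model.exon_count < 3:
        raise CapabilityError(
            f"{model.gene_id}: SE/MXE need >= 3 exons, has {model.exon_count}"
        )
    if n_slot_events > len(slots):
        raise CapabilityError(
            f"{model.gene_id}: {n_slot_events} internal events requested but "
            f"only {len(slots)} separated internal-exon loci available"
        )

    exons = list(model.exons)
    strand = model.strand
    chains = [ref]
    events: list[ASEvent] = []
    slot_iter = iter(slots)
    ap_sides = iter(("start", "end"))

    for k, etype in enumerate(requested):
        variant = list(exons)
        if etype in slot_types:
            i = next(slot_iter)
        if etype == "SE":
            anchor = exons[i]
            del variant[i]
        elif etype == "RI":
            anchor = (exons[i][1], exons[i + 1][0])
            variant[i : i + 2] = [(exons[i][0], exons[i + 1][1])]
        elif etype in ("A5SS", "A3SS"):
            donor_side = (etype == "A5SS") == (strand == "+")
            intron_len = exons[i + 1][0] - exons[i][1]
            if intron_len < ALT_SITE_DELTA + 10:
                raise CapabilityError(
                    f"{model.gene_id}: intron too short for {etype}"
                )
            if donor_side:
                # move the genomic-left (donor on +) boundary of the intron
                s, e = exons[i]
                variant[i] = (s, e + ALT_SITE_DELTA)
                anchor = (
                    (e, e + ALT_SITE_DELTA),
                    exons[i + 1][0],
                )
            else:
                s, e = exons[i + 1]
                variant[i + 1] = (s - ALT_SITE_DELTA, e)
                anchor = (exons[i][1], (s - ALT_SITE_DELTA, s))
        elif etype == "MXE":
            prev_end = exons[i - 1][1]
            room = exons[i][0] - prev_end - 2 * MXE_ALT_GAP
            alt_len = min(MXE_ALT_LEN, room)
            if alt_len < 10:
                raise CapabilityError(
                    f"{model.gene_id}: intron too short to host an MXE exon"
                )
            alt = (prev_end + MXE_ALT_GAP, prev_end + MXE_ALT_GAP + alt_len)
            variant[i] = alt
            anchor = tuple(sorted((alt, exons[i])))
        elif etype == "AP":
            side = next(ap_sides)
            if side == "start":
                s, e = exons[0]
                if e - s <= AP_DELTA + 10:
                    raise CapabilityError(
                        f"{model.gene_id}: first exon too short for AP"
                    )
                variant[0] = (s + AP_DELTA, e)
                anchor = ("start", (s, s + AP_DELTA))
            else:
                s, e = exons[-1]
                if e - s <= AP_DELTA + 10:
                    raise CapabilityError(
                        f"{model.gene_id}: last exon too short for AP"
                    )
                variant[-1] = (s, e - AP_DELTA)
                anchor = ("end", (e - AP_DELTA, e))
        chain_id = f"{model.gene_id}.alt{k}"
        chains.append(ExonChain(model.gene_id, strand, tuple(variant), chain_id))
        events.append(
            ASEvent(
                gene=model.gene_id,
                type=etype,
                anchor=anchor,
                homoeolog=model.subgenome,
                support=(ref.chain_id, chain_id),
            )
        )
    return chains, events


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _stream(config: SimConfig, index: int) -> np.random.Generator:
    """Independent deterministic RNG stream for one generation section."""
    return np.random.default_rng([int(config.seed), index])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(BASES)[rng.integers(0, 4, n)])


def _transcript_positions(exons: Sequence[tuple[int, int]]) -> np.ndarray:
    """Genomic position of every transcript base, in transcript order."""
    return np.concatenate([np.arange(s, e) for s, e in exons])


def _call_probs(alleles: frozenset, error_rate: float) -> np.ndarray:
    """Per-base probability of the observed call at one pileup column."""
    k = len(alleles)
    p = np.zeros(4)
    for a in alleles:
        p[BASES.index(a)] += (1.0 - error_rate) / k
    err_each = error_rate / 3.0
    for a in alleles:
        for j, b in enumerate(BASES):
            if b != a:
                p[j] += err_each / k
    return p


def generate_cohort(config: SimConfig) -> SimBundle:
    """Simulate the full reciprocal-cross study for the given configuration.

    Deterministic for a fixed seed: two calls with the same config produce
    byte-identical tables.
    """
    truth = SimTruth()
    rng_genes = _stream(config, 0)
    rng_snp = _stream(config, 1)

    models_bsb: dict[str, GeneModel] = {}
    models_tc: dict[str, GeneModel] = {}
    sequences: dict[str, str] = {}
    alignments: dict[str, tuple[str, str]] = {}
    snp_rows = []
    neg_rows = []

    elo, ehi = config.exon_len
    ilo, ihi = config.intron_len
    nlo, nhi = config.exons_per_gene

    for g in range(config.n_genes):
        gid_b = f"BSB_g{g:04d}"
        gid_t = f"TC_g{g:04d}"
        pair_id = f"pair{g:04d}"
        truth.ortholog_pairs.append((pair_id, gid_b, gid_t))
        strand = "+" if rng_genes.random() < 0.5 else "-"
        n_ex = int(rng_genes.integers(nlo, nhi + 1))
        exon_lens = rng_genes.integers(elo, ehi + 1, n_ex)
        intron_lens = rng_genes.integers(ilo, ihi + 1, max(n_ex - 1, 0))
        exons = []
        pos = 0
        for i in range(n_ex):
            exons.append((pos, pos + int(exon_lens[i])))
            pos = exons[-1][1] + (int(intron_lens[i]) if i < n_ex - 1 else 0)
        exons = tuple(exons)
        span = exons[-1][1]
        seq_b = _random_seq(rng_genes, span)

        extra = rng_genes.random() < config.extra_exon_frac
        if extra:
            x_intron = int(rng_genes.integers(ilo, ihi + 1))
            x_exon = int(rng_genes.integers(elo, ehi + 1))
            tc_exons = exons + ((span + x_intron, span + x_intron + x_exon),)
            tail = _random_seq(rng_genes, x_intron + x_exon)
        else:
            tc_exons = exons
            tail = ""

        # plant fixed inter-species substitutions on well-covered exonic
        # columns (a read-length margin from the transcript ends keeps
        # per-SNP short-read coverage uniform within the gene)
        tpos = _transcript_positions(exons)
        L = tpos.size
        margin = config.read_length + 20
        seq_t_list = list(seq_b)
        if L > 2 * margin and config.snp_rate > 0:
            eligible = np.arange(margin, L - margin)
            chosen = eligible[rng_snp.random(eligible.size) < config.snp_rate]
        else:
            chosen = np.array([], dtype=int)
        for t_idx in chosen:
            gpos = int(tpos[t_idx])
            b_base = seq_b[gpos]
            others = [x for x in BASES if x != b_base]
            t_base = others[int(rng_snp.integers(0, 3))]
            if rng_snp.random() < config.het_snp_frac:
                third = [x for x in BASES if x not in (b_base, t_base)]
                b_alleles = frozenset(
                    (b_base, third[int(rng_snp.integers(0, 2))])
                )
            else:
                b_alleles = frozenset((b_base,))
            seq_t_list[gpos] = t_base
            snp_rows.append(
                {
                    "pair_id": pair_id,
                    "bsb_pos": gpos,
                    "tc_pos": gpos,
                    "t_idx": int(t_idx),
                    "bsb_alleles": "".join(sorted(b_alleles)),
                    "tc_alleles": t_base,
                    "bsb_base": b_base,
                    "tc_base": t_base,
                }
            )

        # negative pileup columns: not species-specific, must be rejected
        snp_gpos = {int(tpos[t]) for t in chosen}
        candidates = [int(p) for p in tpos[margin : L - margin : 37] if int(p) not in snp_gpos]
        for reason, gpos in zip(("overlapping_het", "monomorphic", "dropout"), candidates):
            base = seq_b[gpos]
            others = [x for x in BASES if x != base]
            if reason == "overlapping_het":
                alt = others[int(rng_snp.integers(0, 3))]
                b_all, t_all = "".join(sorted({base, alt})), base
            elif reason == "monomorphic":
                b_all, t_all = base, base
            else:  # true difference, but one parent replicate has no coverage
                alt = others[int(rng_snp.integers(0, 3))]
                b_all, t_all = base, alt
                seq_t_list[gpos] = alt
            neg_rows.append(
                {
                    "pair_id": pair_id,
                    "bsb_pos": gpos,
                    "tc_pos": gpos,
                    "bsb_alleles": b_all,
                    "tc_alleles": t_all,
                    "reason": reason,
                }
            )

        seq_t = "".join(seq_t_list) + tail
        L_t = L + (tc_exons[-1][1] - tc_exons[-1][0] if extra else 0)
        models_bsb[gid_b] = GeneModel(gid_b, BSB, strand, exons, int(0.8 * L))
        models_tc[gid_t] = GeneModel(gid_t, TC, strand, tc_exons, int(0.8 * L_t))
        sequences[gid_b] = seq_b
        sequences[gid_t] = seq_t
        alignments[pair_id] = (seq_b + "-" * len(tail), seq_t)

    truth.snps = pd.DataFrame(
        snp_rows,
        columns=[
            "pair_id",
            "bsb_pos",
            "tc_pos",
            "t_idx",
            "bsb_alleles",
            "tc_alleles",
            "bsb_base",
            "tc_base",
        ],
    )
    truth.negative_columns = pd.DataFrame(
        neg_rows,
        columns=["pair_id", "bsb_pos", "tc_pos", "bsb_alleles", "tc_alleles", "reason"],
    )

    # homoeolog bias and between-hybrid DE assignments
    rng_fx = _stream(config, 7)
    n = config.n_genes
    perm = rng_fx.permutation(n)
    n_bias = int(round(config.bias_frac * n))
    n_de = int(round(config.de_frac * n))
    bias_ids = {f"pair{i:04d}" for i in perm[:n_bias]}
    de_ids = {f"pair{i:04d}": int(s) for i, s in zip(
        rng_fx.permutation(n)[:n_de], rng_fx.choice([-1, 1], n_de)
    )}
    bias_signs = {p: int(s) for p, s in zip(sorted(bias_ids), rng_fx.choice([-1, 1], n_bias))}
    for pair_id, _, _ in truth.ortholog_pairs:
        b = config.bias_log2 * bias_signs.get(pair_id, 0) if pair_id in bias_ids else 0.0
        for tissue in TISSUES:
            truth.gene_bias_log2[(pair_id, tissue)] = b
    truth.de_genes = de_ids

    # isoform chains and planted AS events, rotated over event types so each
    # class accrues events across the cohort
    rng_as = _stream(config, 8)
    for g, (pair_id, gid_b, gid_t) in enumerate(truth.ortholog_pairs):
        model_b = models_bsb[gid_b]
        capacity = len(_slots(model_b))
        order = [NAMED_AS_TYPES[(g + k) % len(NAMED_AS_TYPES)] for k in range(len(NAMED_AS_TYPES))]
        chosen: list[str] = []
        used_slots = 0
        for etype in order:
            if etype == "AP":
                if chosen.count("AP") < 1:
                    chosen.append(etype)
            elif used_slots < capacity:
                chosen.append(etype)
                used_slots += 1
        spec = {t: chosen.count(t) for t in set(chosen)}
        event_total = sum(config.as_events_per_gene.values())
        if event_total == 0:
            spec = {}
        chains_b, events_b = plant_as_isoforms(model_b, spec)
        truth.chains[gid_b] = chains_b
        truth.as_events[gid_b] = events_b

        shared = rng_as.random() < config.shared_as_frac and bool(events_b)
        model_t = models_tc[gid_t]
        if shared:
            # mirror the BSB chains through the (identity) coordinate map,
            # appending the TC-private terminal exon to every chain
            tail_exons = model_t.exons[len(model_b.exons):]
            chains_t = []
            for ch in chains_b:
                cid = ch.chain_id.replace(gid_b, gid_t)
                chains_t.append(
                    ExonChain(gid_t, model_t.strand, ch.exons + tail_exons, cid)
                )
            events_t = [
                dataclasses.replace(
                    ev,
                    gene=gid_t,
                    homoeolog=TC,
                    support=tuple(s.replace(gid_b, gid_t) for s in ev.support),
                )
                for ev in events_b
            ]
            truth.shared_as_pairs.add(pair_id)
        else:
            chains_t = [model_t.chain(f"{gid_t}.ref")]
            events_t = []
        truth.chains[gid_t] = chains_t
        truth.as_events[gid_t] = events_t

    bundle = SimBundle(
        config=config,
        truth=truth,
        models_bsb=models_bsb,
        models_tc=models_tc,
        sequences=sequences,
        alignments=alignments,
    )
    bundle.pileups = simulate_parental_pileups(bundle)
    bundle.short_reads = simulate_reads(bundle, "short")
    bundle.long_reads = simulate_reads(bundle, "long")

    rng_mito = _stream(config, 5)
    for hybrid in HYBRIDS:
        maternal = truth.maternal[hybrid]
        n_mat = int(rng_mito.binomial(config.mito_reads, config.mito_purity))
        counts = {maternal: n_mat}
        other = TC if maternal == BSB else BSB
        counts[other] = config.mito_reads - n_mat
        bundle.mito_counts[hybrid] = (counts[BSB], counts[TC])
    return bundle


def simulate_parental_pileups(bundle: SimBundle) -> pd.DataFrame:
    """Per-column base counts for each parent and replicate.

    Rows are restricted to polymorphic-candidate columns (the planted SNPs
    plus the planted negative columns), which is what a variant-calling
    front-end would hand downstream.
    """
    config = bundle.config
    rng = _stream(config, 2)
    rows = []
    snp_df = bundle.truth.snps
    neg_df = bundle.truth.negative_columns
    columns = []
    if len(snp_df):
        for rec in snp_df.itertuples():
            columns.append(
                (rec.pair_id, rec.bsb_pos, rec.tc_pos, rec.bsb_alleles, rec.tc_alleles, "")
            )
    if len(neg_df):
        for rec in neg_df.itertuples():
            columns.append(
                (rec.pair_id, rec.bsb_pos, rec.tc_pos, rec.bsb_alleles, rec.tc_alleles, rec.reason)
            )
    for pair_id, bpos, tpos, b_alleles, t_alleles, reason in columns:
        for parent, pos, alleles in ((BSB, bpos, b_alleles), (TC, tpos, t_alleles)):
            probs = _call_probs(frozenset(alleles), config.error_rate)
            for rep in REPLICATES:
                if reason == "dropout" and parent == TC and rep == 2:
                    cov = 0
                else:
                    cov = max(1, int(rng.poisson(config.parent_depth)))
                counts = rng.multinomial(cov, probs) if cov else np.zeros(4, dtype=int)
                rows.append(
                    {
                        "pair_id": pair_id,
                        "parent": parent,
                        "replicate": rep,
                        "pos": int(pos),
                        "A": int(counts[0]),
                        "C": int(counts[1]),
                        "G": int(counts[2]),
                        "T": int(counts[3]),
                    }
                )
    return pd.DataFrame(
        rows, columns=["pair_id", "parent", "replicate", "pos", "A", "C", "G", "T"]
    )


def _gene_snp_arrays(bundle: SimBundle) -> dict:
    """Per-pair sorted SNP arrays used during read simulation."""
    out = {}
    df = bundle.truth.snps
    for pair_id, sub in df.groupby("pair_id", sort=True):
        sub = sub.sort_values("t_idx")
        out[pair_id] = (
            sub["t_idx"].to_numpy(),
            sub["bsb_pos"].to_numpy(),
            sub["bsb_base"].to_numpy(),
            sub["tc_base"].to_numpy(),
        )
    return out


def _maybe_flip(base: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate > 0 and rng.random() < error_rate:
        others = [x for x in BASES if x != base]
        return others[int(rng.integers(0, 3))]
    return base


def simulate_reads(bundle: SimBundle, kind: str) -> pd.DataFrame:
    """Simulate the ``short`` (replicated Illumina-like) or ``long``
    (pooled full-length candidate) read tables for a cohort.

    Deterministic given the bundle's config; re-running returns an identical
    table.  Short-read simulation also (re)records the planted outlier SNP
    cells in the bundle's truth.
    """
    if kind == "short":
        return _simulate_short(bundle)
    if kind == "long":
        return _simulate_long(bundle)
    raise ConfigError(f"kind must be 'short' or 'long', got {kind!r}")


def _simulate_short(bundle: SimBundle) -> pd.DataFrame:
    config = bundle.config
    rng = _stream(config, 3)
    rng_out = _stream(config, 6)
    snp_arrays = _gene_snp_arrays(bundle)
    truth = bundle.truth
    rl = config.read_length
    rows = []
    counter = 0

    tr_len = {}
    for pair_id, gid_b, gid_t in truth.ortholog_pairs:
        tr_len[pair_id] = (
            bundle.models_bsb[gid_b].transcript_length,
            bundle.models_tc[gid_t].transcript_length,
        )

    def emit(pair_id, hybrid, tissue, rep, start, origin):
        nonlocal counter
        arrays = snp_arrays.get(pair_id)
        calls = []
        if arrays is not None:
            t_idx, gpos, b_base, t_base = arrays
            lo = int(np.searchsorted(t_idx, start))
            hi = int(np.searchsorted(t_idx, start + rl))
            own = b_base if origin == BSB else t_base
            for k in range(lo, hi):
                base = _maybe_flip(str(own[k]), rng, config.error_rate)
                calls.append(f"{int(gpos[k])}:{base}")
        rows.append(
            (
                f"sr{counter:08d}",
                pair_id,
                hybrid,
                tissue,
                rep,
                int(start),
                int(start) + rl,
                origin,
                ";".join(calls),
            )
        )
        counter += 1

    for hybrid in HYBRIDS:
        for tissue in TISSUES:
            for rep in REPLICATES:
                for pair_id, gid_b, gid_t in truth.ortholog_pairs:
                    bias = truth.gene_bias_log2[(pair_id, tissue)]
                    p_bsb = 2.0 ** bias / (1.0 + 2.0 ** bias)
                    mu = config.depth
                    direction = truth.de_genes.get(pair_id)
                    if direction is not None and hybrid == "TBF3":
                        mu *= 2.0 ** (config.de_log2 * direction)
                    n = int(rng.poisson(mu))
                    if n == 0:
                        continue
                    origins = rng.random(n) < p_bsb
                    l_b, l_t = tr_len[pair_id]
                    for is_bsb in origins:
                        L = l_b if is_bsb else l_t
                        start = int(rng.integers(0, max(L - rl, 0) + 1))
                        emit(
                            pair_id,
                            hybrid,
                            tissue,
                            rep,
                            start,
                            BSB if is_bsb else TC,
                        )

    # planted outlier cells: one replicate of one library gets an inflated
    # read count at the SNP
    truth.outlier_cells = []
    if config.outlier_snp_rate > 0 and len(truth.snps):
        for rec in truth.snps.itertuples():
            if rng_out.random() >= config.outlier_snp_rate:
                continue
            hybrid = HYBRIDS[int(rng_out.integers(0, len(HYBRIDS)))]
            tissue = TISSUES[int(rng_out.integers(0, len(TISSUES)))]
            rep = int(rng_out.integers(1, 4))
            l_b, _ = tr_len[rec.pair_id]
            per_snp = config.depth * rl / max(l_b, rl)
            extra = int(round((config.outlier_inflation - 1.0) * per_snp))
            bias = truth.gene_bias_log2[(rec.pair_id, tissue)]
            p_bsb = 2.0 ** bias / (1.0 + 2.0 ** bias)
            # the abnormal pileup is local to the SNP (a mutation-site
            # artifact), so the extra reads cover only that column and do
            # not inflate neighbouring SNPs of the gene
            start = int(rec.t_idx)
            for _ in range(extra):
                origin = BSB if rng_out.random() < p_bsb else TC
                own = rec.bsb_base if origin == BSB else rec.tc_base
                call = _maybe_flip(str(own), rng_out, config.error_rate)
                rows.append(
                    (
                        f"sr{counter:08d}",
                        rec.pair_id,
                        hybrid,
                        tissue,
                        rep,
                        start,
                        start + 1,
                        origin,
                        f"{int(rec.bsb_pos)}:{call}",
                    )
                )
                counter += 1
            truth.outlier_cells.append(
                (rec.pair_id, int(rec.bsb_pos), hybrid, tissue, rep)
            )

    return pd.DataFrame(rows, columns=_SHORT_READ_COLUMNS)


def _chain_snp_calls(
    chain: ExonChain,
    snp_gpos: np.ndarray,
    own_base: np.ndarray,
    rng: np.random.Generator,
    error_rate: float,
) -> str:
    calls = []
    for s, e in chain.exons:
        lo = int(np.searchsorted(snp_gpos, s))
        hi = int(np.searchsorted(snp_gpos, e))
        for k in range(lo, hi):
            base = _maybe_flip(str(own_base[k]), rng, error_rate)
            calls.append(f"{int(snp_gpos[k])}:{base}")
    return ";".join(calls)


def _simulate_long(bundle: SimBundle) -> pd.DataFrame:
    config = bundle.config
    rng = _stream(config, 4)
    truth = bundle.truth
    rows = []
    counter = 0
    snp_df = bundle.truth.snps
    by_pair = {
        pair_id: sub.sort_values("bsb_pos")
        for pair_id, sub in snp_df.groupby("pair_id", sort=True)
    } if len(snp_df) else {}

    for pair_id, gid_b, gid_t in truth.ortholog_pairs:
        sub = by_pair.get(pair_id)
        if sub is not None:
            gpos = sub["bsb_pos"].to_numpy()
            base_b = sub["bsb_base"].to_numpy()
            base_t = sub["tc_base"].to_numpy()
        else:
            gpos = np.array([], dtype=int)
            base_b = base_t = np.array([], dtype=object)
        for hybrid in HYBRIDS:
            for gid, origin, own in ((gid_b, BSB, base_b), (gid_t, TC, base_t)):
                for chain in truth.chains[gid]:
                    for _ in range(config.long_reads_per_chain):
                        f5 = rng.random() < config.fl_flag_rate
                        f3 = rng.random() < config.fl_flag_rate
                        pa = rng.random() < config.fl_flag_rate
                        calls = _chain_snp_calls(
                            chain, gpos, own, rng, config.error_rate
                        )
                        read_id = f"lr{counter:07d}"
                        counter += 1
                        length = chain.length
                        rows.append(
                            {
                                "read_id": read_id,
                                "hybrid": hybrid,
                                "gene": gid,
                                "pair_id": pair_id,
                                "length": length,
                                "has_5prime_primer": f5,
                                "has_3prime_primer": f3,
                                "has_polyA": pa,
                                "chain_id": chain.chain_id,
                                "exons": ",".join(f"{s}-{e}" for s, e in chain.exons),
                                "strand": chain.strand,
                                "calls": calls,
                                "true_origin": origin,
                            }
                        )
                        truth.long_read_origin[read_id] = origin
                        truth.long_read_fl[read_id] = bool(
                            length > 300 and f5 and f3 and pa
                        )
    return pd.DataFrame(rows)
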