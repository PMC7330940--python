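"""Reading and writing of the pipeline's tabular and annotation formats.

Every emitted table carries ``#`` header lines stamping the seed and the
configuration hash, so a rerun with the same configuration is
byte-identical and self-describing.
"""

from __future__ import annotations

import hashlib
import io
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import GeneModel, SpeciesSNP


def config_hash(config_mapping: Mapping) -> str:
    """Stable short hash of a configuration mapping."""
    canon = yaml.safe_dump(
        {k: _plain(v) for k, v in sorted(dict(config_mapping).items())},
        sort_keys=True,
    )
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _plain(value):
    if isinstance(value, tuple):
        return list(value)
    if isinstance(value, Mapping):
        return {k: _plain(v) for k, v in sorted(value.items())}
    if hasattr(value, "item"):
        return value.item()
    return value


def write_tsv(df: pd.DataFrame, path: Path, meta: Mapping | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = io.StringIO()
    for key, value in (meta or {}).items():
        buf.write(f"# {key}={value}\n")
    df.to_csv(buf, sep="\t", index=False)
    path.write_text(buf.getvalue())


def read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_gtf(
    models: Iterable[GeneModel], path: Path, meta: Mapping | None = None
) -> None:
    """Emit gene models as GTF (1-based, inclusive coordinates)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# {k}={v}" for k, v in (meta or {}).items()]
    for m in sorted(models, key=lambda m: m.gene_id):
        attrs = f'gene_id "{m.gene_id}"; cds_length "{m.cds_length}";'
        span = (m.exons[0][0] + 1, m.exons[-1][1])
        lines.append(
            "\t".join(
                [m.gene_id, "homoeosplice", "gene", str(span[0]), str(span[1]),
                 ".", m.strand, ".", attrs]
            )
        )
        for i, (s, e) in enumerate(m.exons, start=1):
            attrs_e = f'gene_id "{m.gene_id}"; exon_number "{i}";'
            lines.append(
                "\t".join(
                    [m.gene_id, "homoeosplice", "exon", str(s + 1), str(e),
                     ".", m.strand, ".", attrs_e]
                )
            )
    path.write_text("\n".join(lines) + "\n")


def read_gtf(path: Path) -> dict[str, GeneModel]:
    """Parse the gene models written by :func:`write_gtf`."""
    exons: dict[str, list] = {}
    strands: dict[str, str] = {}
    cds: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        feature, start, end, strand, attrs = (
            fields[2], int(fields[3]), int(fields[4]), fields[6], fields[8]
        )
        gene_id = attrs.split('gene_id "')[1].split('"')[0]
        strands[gene_id] = strand
        if feature == "gene" and 'cds_length "' in attrs:
            cds[gene_id] = int(attrs.split('cds_length "')[1].split('"')[0])
        elif feature == "exon":
            exons.setdefault(gene_id, []).append((start - 1, end))
    out = {}
    for gene_id, ex in exons.items():
        subgenome = "TC" if gene_id.startswith("TC") else "BSB"
        out[gene_id] = GeneModel(
            gene_id, subgenome, strands[gene_id], tuple(sorted(ex)),
            cds.get(gene_id, 0),
        )
    return out


def write_fasta(seqs: Mapping[str, str], path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(seqs.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def snps_from_frame(df: pd.DataFrame) -> list[SpeciesSNP]:
    """Rebuild SpeciesSNP objects from the tabular (1-based) SNP table."""
    return [
        SpeciesSNP(
            pair_id=rec.pair_id,
            bsb_pos=int(rec.bsb_pos1) - 1,
            tc_pos=int(rec.tc_pos1) - 1,
            bsb_alleles=frozenset(rec.bsb_alleles),
            tc_alleles=frozenset(rec.tc_alleles),
            bsb_coverage=tuple(int(x) for x in str(rec.bsb_cov).split(",")),
            tc_coverage=tuple(int(x) for x in str(rec.tc_cov).split(",")),
        )
        for rec in df.itertuples()
    ]


def exons_to_str(exons: Iterable[tuple[int, int]]) -> str:
    return ",".join(f"{s}-{e}" for s, e in exons)


def exons_from_str(text: str) -> tuple[tuple[int, int], ...]:
    return tuple(
        (int(a), int(b))
        for a, b in (part.split("-") for part in text.split(","))
    )


def write_events_bed(events, path: Path, meta: Mapping | None = None) -> None:
    """BED export of event anchor intervals (gene-relative coordinates)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# {k}={v}" for k, v in (meta or {}).items()]

    def intervals(anchor):
        if isinstance(anchor, tuple):
            if (
                len(anchor) == 2
                and all(isinstance(x, int) for x in anchor)
                and anchor[0] < anchor[1]
            ):
                yield anchor
            else:
                for part in anchor:
                    yield from intervals(part)

    for ev in events:
        for s, e in intervals(ev.anchor):
            lines.append(
                f"{ev.gene}\t{s}\t{e}\t{ev.type}\t0\t+"
            )
    path.write_text("\n".join(lines) + "\n")
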