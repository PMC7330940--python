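"""Ortholog pairing between the two parental gene sets and comparative
gene-structure statistics.

Pairing uses reciprocal-best-hit (RBH) selection over a directed similarity
table: a pair is emitted iff each gene is the unique best-scoring hit of the
other and both directed hits pass the significance threshold.  The
similarity table is an input; for synthetic sequence sets an in-repo k-mer
containment scorer is provided so no external aligner is needed.
"""

from __future__ import annotations

import logging
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    BSB,
    TC,
    GeneModel,
    InputShapeError,
    OrthologPair,
    StatisticsError,
)

logger = logging.getLogger(__name__)

MIN_TRANSCRIPT_LENGTH = 100
RBH_EVALUE_THRESHOLD = 1e-5


def filter_transcripts(models: Iterable[GeneModel]) -> list[GeneModel]:
    """Drop transcripts lacking an annotated CDS or shorter than 100 bp.

    Retained iff ``cds_length > 0`` and total transcript length >= 100 bp
    (the length cut is strict: 99 bp is discarded, 100 bp is kept).
    """
    return [
        m
        for m in models
        if m.cds_length > 0 and m.transcript_length >= MIN_TRANSCRIPT_LENGTH
    ]


def _best_hits(hits: pd.DataFrame, threshold: float) -> dict[str, str]:
    """Unique best subject per query among threshold-passing hits.

    Queries whose top score is tied between several subjects are excluded
    (logged), so they can never enter a pair.
    """
    best: dict[str, str] = {}
    passing = hits[hits["evalue"] <= threshold]
    for query, sub in passing.groupby("query", sort=False):
        top = sub["score"].max()
        winners = sub.loc[sub["score"] == top, "subject"].unique()
        if len(winners) > 1:
            logger.warning(
                "gene %s excluded from RBH: best hit tied among %d subjects",
                query,
                len(winners),
            )
            continue
        best[query] = winners[0]
    return best


def reciprocal_best_hits(
    score_table: pd.DataFrame,
    threshold: float = RBH_EVALUE_THRESHOLD,
    subgenome_of: Callable[[str], str] | None = None,
) -> list[OrthologPair]:
    """Pair genes that are each other's unique best hit.

    ``score_table`` holds directed hits with columns ``query``, ``subject``,
    ``score``, ``evalue``; both directions must be present for a pair to
    form.  Output is sorted by BSB gene id; the subgenome of a gene id is
    taken from ``subgenome_of`` (default: a ``BSB``/``TC`` id prefix).
    """
    required = {"query", "subject", "score", "evalue"}
    if not required.issubset(score_table.columns):
        raise InputShapeError(
            f"score table must have columns {sorted(required)}"
        )
    if subgenome_of is None:
        subgenome_of = lambda g: TC if str(g).startswith(TC) else BSB  # noqa: E731
    best = _best_hits(score_table, threshold)
    scores = {
        (r.query, r.subject): (float(r.score), float(r.evalue))
        for r in score_table.itertuples()
    }
    pairs = []
    for a, b in best.items():
        if best.get(b) != a:
            continue
        if subgenome_of(a) != BSB:
            continue  # emit each mutual pair once, from its BSB side
        if subgenome_of(b) != TC:
            continue
        score, evalue = scores[(a, b)]
        pairs.append(OrthologPair(a, b, score, evalue))
    pairs.sort(key=lambda p: p.bsb_gene)
    return pairs


def kmer_containment_scores(
    seqs_bsb: Mapping[str, str],
    seqs_tc: Mapping[str, str],
    k: int = 11,
) -> pd.DataFrame:
    """Directed all-against-all k-mer containment similarity table.

    ``score(q, s)`` is the fraction of the query's k-mers found in the
    subject; the significance proxy decays exponentially in the score so a
    containment above ~0.4 clears the default RBH threshold.
    """
    def kmers(seq: str) -> set:
        return {seq[i : i + k] for i in range(len(seq) - k + 1)}

    sets_b = {g: kmers(s) for g, s in seqs_bsb.items()}
    sets_t = {g: kmers(s) for g, s in seqs_tc.items()}
    rows = []
    for qset, sset in ((sets_b, sets_t), (sets_t, sets_b)):
        for q, qk in qset.items():
            if not qk:
                continue
            for s, sk in sset.items():
                inter = len(qk & sk)
                if inter == 0:
                    continue
                score = inter / len(qk)
                rows.append(
                    {
                        "query": q,
                        "subject": s,
                        "score": score,
                        "evalue": float(np.exp(-30.0 * score)),
                    }
                )
    return pd.DataFrame(rows, columns=["query", "subject", "score", "evalue"])


def structure_stats(
    pairs: Iterable[OrthologPair],
    models: Mapping[str, GeneModel],
) -> dict:
    """Comparative exon-number / CDS-length statistics over ortholog pairs.

    Returns per-subgenome means, equal-value tallies, Wilcoxon signed-rank
    p-values for the paired differences, and the within-subgenome Pearson
    correlation of exon number with CDS length.
    """
    pairs = list(pairs)
    if len(pairs) < 3:
        raise StatisticsError("need at least 3 ortholog pairs for statistics")
    for p in pairs:
        if p.bsb_gene not in models or p.tc_gene not in models:
            raise InputShapeError(f"missing gene model for pair {p.pair_id}")
    ex_b = np.array([models[p.bsb_gene].exon_count for p in pairs], dtype=float)
    ex_t = np.array([models[p.tc_gene].exon_count for p in pairs], dtype=float)
    cds_b = np.array([models[p.bsb_gene].cds_length for p in pairs], dtype=float)
    cds_t = np.array([models[p.tc_gene].cds_length for p in pairs], dtype=float)

    def paired_p(x: np.ndarray, y: np.ndarray) -> float:
        diff = x - y
        if np.all(diff == 0):
            return 1.0  # no signed ranks: no evidence of any difference
        return float(stats.wilcoxon(x, y, zero_method="wilcox").pvalue)

    def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        if np.std(x) == 0 or np.std(y) == 0:
            return float("nan"), float("nan")
        r = stats.pearsonr(x, y)
        return float(r.statistic), float(r.pvalue)

    r_b, p_rb = pearson(ex_b, cds_b)
    r_t, p_rt = pearson(ex_t, cds_t)
    return {
        "n_pairs": len(pairs),
        "mean_exon_number": {BSB: float(ex_b.mean()), TC: float(ex_t.mean())},
        "mean_cds_length": {BSB: float(cds_b.mean()), TC: float(cds_t.mean())},
        "n_equal_exon_number": int(np.sum(ex_b == ex_t)),
        "n_equal_cds_length": int(np.sum(cds_b == cds_t)),
        "p_exon_number": paired_p(ex_b, ex_t),
        "p_cds_length": paired_p(cds_b, cds_t),
        "pearson_r": {BSB: r_b, TC: r_t},
        "pearson_p": {BSB: p_rb, TC: p_rt},
    }
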