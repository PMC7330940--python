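"""Homoeolog differential expression between the two hybrids.

Counts are tested with an exact negative-binomial test under a common
dispersion, the count-data analogue of Fisher's exact test: replicate
counts are scaled to a common library size, each group's sum is NB
distributed with size n/phi, and the test conditions on the pooled total,
summing the probabilities of all splits no more probable than the observed
one (two-sided by probability mass, no doubling).  With phi = 0 this
reduces exactly to a conditional binomial test.  P-values are adjusted with
the Benjamini-Hochberg step-up procedure and genes are called differential
at FDR <= 0.05.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .types import BSB, TC, InputShapeError, IntegrityError, StatisticsError

logger = logging.getLogger(__name__)

FDR_THRESHOLD = 0.05
_TIE_REL_TOL = 1e-10


def scale_to_common_library(
    counts: np.ndarray, lib_sizes: np.ndarray
) -> np.ndarray:
    """Scale a genes x libraries count matrix to the geometric-mean library
    size and round to integers (the exact test requires exchangeable sums)."""
    counts = np.asarray(counts, dtype=float)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if np.any(lib_sizes <= 0):
        raise StatisticsError("library sizes must be positive")
    target = np.exp(np.mean(np.log(lib_sizes)))
    return np.rint(counts * (target / lib_sizes)).astype(np.int64)


def estimate_common_dispersion(
    counts: np.ndarray, lib_sizes: np.ndarray | None = None
) -> float:
    """Pooled method-of-moments estimate of the common NB dispersion.

    For each gene with positive mean m and sample variance s^2 on
    library-size-scaled counts, the per-gene moment estimate is
    max(0, (s^2 - m) / m^2); the common dispersion is their mean.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise InputShapeError("counts must be a genes x libraries matrix")
    if lib_sizes is not None:
        counts = scale_to_common_library(counts, lib_sizes).astype(float)
    m = counts.mean(axis=1)
    if np.all(m == 0):
        raise StatisticsError("all-zero count matrix: cannot estimate dispersion")
    s2 = counts.var(axis=1, ddof=1)
    pos = m > 0
    per_gene = np.maximum(0.0, (s2[pos] - m[pos]) / m[pos] ** 2)
    return float(per_gene.mean())


def _conditional_logpmf(t: int, r_a: float, r_b: float) -> np.ndarray:
    """Log P(S_a = k | S_a + S_b = t) for k = 0..t under equal-mean NB sums
    with sizes r_a and r_b (negative-hypergeometric form; the NB probability
    parameter cancels under the null)."""
    k = np.arange(t + 1)
    logp = (
        gammaln(k + r_a)
        - gammaln(k + 1)
        - gammaln(r_a)
        + gammaln(t - k + r_b)
        - gammaln(t - k + 1)
        - gammaln(r_b)
    )
    return logp - logsumexp(logp)


def nb_exact_test(
    group_a: Sequence[int],
    group_b: Sequence[int],
    phi: float,
) -> float:
    """Two-sided exact test of equal means for two groups of NB counts.

    Inputs are pre-scaled to equal effective library sizes.  Conditions on
    the pooled total and sums the conditional probabilities of every split
    whose probability does not exceed the observed split's.
    """
    a = np.asarray(group_a, dtype=np.int64)
    b = np.asarray(group_b, dtype=np.int64)
    if np.any(a < 0) or np.any(b < 0):
        raise InputShapeError("counts must be non-negative")
    if phi < 0:
        raise InputShapeError("dispersion must be non-negative")
    s_a, s_b = int(a.sum()), int(b.sum())
    t = s_a + s_b
    if t == 0:
        return 1.0
    if phi < 1e-12:
        # Poisson limit: conditional distribution is binomial
        n_a, n_b = len(a), len(b)
        k = np.arange(t + 1)
        logp = (
            gammaln(t + 1)
            - gammaln(k + 1)
            - gammaln(t - k + 1)
            + k * np.log(n_a / (n_a + n_b))
            + (t - k) * np.log(n_b / (n_a + n_b))
        )
        logp = logp - logsumexp(logp)
    else:
        logp = _conditional_logpmf(t, len(a) / phi, len(b) / phi)
    p_obs = logp[s_a]
    mask = logp <= p_obs + np.log1p(_TIE_REL_TOL)
    return float(min(1.0, np.exp(logsumexp(logp[mask]))))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment with monotonicity."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise InputShapeError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    ranked = np.minimum(ranked, 1.0)
    out = np.empty(n)
    out[order] = ranked
    return out


def call_degs(results: pd.DataFrame, threshold: float = FDR_THRESHOLD) -> pd.DataFrame:
    """Flag differential genes at the FDR threshold and set directions."""
    out = results.copy()
    out["deg"] = out["fdr"] <= threshold
    direction = np.where(out["log2fc"] > 0, "up-in-TBF3", "up-in-BTF3")
    out["direction"] = np.where(out["deg"], direction, "ns")
    return out


def differential_expression(
    matrix: pd.DataFrame,
    homoeolog: str,
    tissue: str,
    genes: Iterable[str] | None = None,
    phi: float | None = None,
    fdr_threshold: float = FDR_THRESHOLD,
) -> pd.DataFrame:
    """Test one homoeolog in one tissue for DE between the two hybrids.

    ``matrix`` is the tidy homoeolog count matrix (gene x hybrid x tissue x
    replicate).  ``genes`` restricts the test to an expression-filtered
    set; ``phi`` overrides the pooled dispersion estimate.  log2 fold
    change is TBF3 over BTF3 on common-scale counts with a half-count
    offset; log2 CPM is the average over all six libraries.
    """
    col = "bsb_count" if homoeolog == BSB else "tc_count"
    cpm_col = "bsb_cpm" if homoeolog == BSB else "tc_cpm"
    sub = matrix[matrix["tissue"] == tissue]
    if sub.empty:
        raise IntegrityError(f"no counts for tissue {tissue!r}")
    wide = sub.pivot_table(
        index="pair_id", columns=["hybrid", "replicate"], values=col, aggfunc="sum"
    ).fillna(0)
    hybrids = sorted({c[0] for c in wide.columns})
    if set(hybrids) != {"TBF3", "BTF3"}:
        raise IntegrityError("matrix must contain both hybrids")
    if genes is not None:
        genes = [g for g in genes if g in wide.index]
        wide = wide.loc[genes]
    lib_sizes = (
        sub.groupby(["hybrid", "replicate"])[["bsb_count", "tc_count"]]
        .sum()
        .sum(axis=1)
    )
    lib_vec = np.array([lib_sizes[c] for c in wide.columns], dtype=float)
    scaled = scale_to_common_library(wide.to_numpy(), lib_vec)
    if phi is None:
        phi = estimate_common_dispersion(scaled.astype(float))
    cols_a = [i for i, c in enumerate(wide.columns) if c[0] == "TBF3"]
    cols_b = [i for i, c in enumerate(wide.columns) if c[0] == "BTF3"]
    has_cpm = cpm_col in sub.columns
    if has_cpm:
        cpm_mean = sub.groupby("pair_id")[cpm_col].mean()
    rows = []
    for i, gene in enumerate(wide.index):
        a = scaled[i, cols_a]
        b = scaled[i, cols_b]
        p = nb_exact_test(a, b, phi)
        log2fc = float(np.log2((a.mean() + 0.5) / (b.mean() + 0.5)))
        if has_cpm:
            log2cpm = float(np.log2(cpm_mean.get(gene, 0.0) + 0.5))
        else:
            log2cpm = float("nan")
        rows.append(
            {
                "pair_id": gene,
                "homoeolog": homoeolog,
                "tissue": tissue,
                "log2fc": log2fc,
                "log2cpm": log2cpm,
                "p_value": p,
            }
        )
    results = pd.DataFrame(
        rows, columns=["pair_id", "homoeolog", "tissue", "log2fc", "log2cpm", "p_value"]
    )
    results["fdr"] = bh_adjust(results["p_value"].to_numpy()) if len(results) else []
    results["phi"] = phi
    return call_degs(results, fdr_threshold)


def shared_deg_summary(
    bsb_degs: pd.DataFrame,
    tc_degs: pd.DataFrame,
    known_pairs: Iterable[str] | None = None,
) -> dict:
    """Venn counts of DEG sets over ortholog pairs plus direction concordance.

    ``bsb_degs``/``tc_degs`` are DE tables for one tissue (rows keyed by
    ``pair_id`` with ``deg`` and ``direction`` columns).
    """
    if known_pairs is not None:
        known = set(known_pairs)
        for frame, label in ((bsb_degs, BSB), (tc_degs, TC)):
            unknown = set(frame["pair_id"]) - known
            if unknown:
                raise IntegrityError(
                    f"{label} DE table contains genes outside the ortholog "
                    f"table: {sorted(unknown)[:5]}"
                )
    set_b = set(bsb_degs.loc[bsb_degs["deg"], "pair_id"])
    set_t = set(tc_degs.loc[tc_degs["deg"], "pair_id"])
    shared = set_b & set_t
    dir_b = bsb_degs.set_index("pair_id")["direction"]
    dir_t = tc_degs.set_index("pair_id")["direction"]
    same = sum(1 for g in shared if dir_b[g] == dir_t[g])
    return {
        "bsb_only": len(set_b - set_t),
        "tc_only": len(set_t - set_b),
        "shared": len(shared),
        "direction_concordance": (same / len(shared)) if shared else float("nan"),
    }
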