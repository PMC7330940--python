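"""Read partitioning, SNP counting, outlier filtering and normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from homoeosplice import (
    SimConfig,
    assign_short_read,
    filter_outlier_snps,
    gene_homoeolog_counts,
    generate_cohort,
    mito_origin_check,
    normalize_and_filter,
    snp_allele_counts,
)
from homoeosplice.quant import SNP_COUNT_COLUMNS, assign_reads_frame, snp_lookup
from homoeosplice.snp_discovery import build_coordinate_map, call_species_snps
from homoeosplice.types import BSB, TC, IntegrityError, StatisticsError

SNPS = {
    10: (frozenset("A"), frozenset("G")),
    20: (frozenset("C"), frozenset("T")),
    30: (frozenset("AT"), frozenset("G")),
    40: (frozenset("G"), frozenset("C")),
}


def discovered_snps(bundle):
    snps = []
    for pair_id, sub in bundle.pileups.groupby("pair_id"):
        cmap = build_coordinate_map(pair_id, *bundle.alignments[pair_id])
        snps.extend(call_species_snps(cmap, sub))
    return snps


class TestAssignShortRead:
    def test_unanimous_bsb(self):
        a = assign_short_read([(10, "A"), (20, "C"), (30, "T")], SNPS)
        assert a.call == BSB
        assert (a.covered, a.matches_bsb, a.matches_tc) == (3, 3, 0)

    def test_tie_is_ambiguous(self):
        a = assign_short_read(
            [(10, "A"), (20, "C"), (30, "G"), (40, "C")], SNPS
        )
        assert a.matches_bsb == a.matches_tc == 2
        assert a.call == "ambiguous"

    def test_no_covered_snps_is_ambiguous(self):
        assert assign_short_read([], SNPS).call == "ambiguous"

    def test_majority_matching_neither_parent_is_ambiguous(self):
        # two of three alleles are error bases matching neither parent
        a = assign_short_read([(10, "T"), (20, "G"), (30, "A")], SNPS)
        assert a.call == "ambiguous"

    def test_strict_majority_wins(self):
        a = assign_short_read([(10, "A"), (20, "C"), (30, "G")], SNPS)
        assert a.call == BSB  # 2 BSB vs 1 TC

    def test_unknown_position_is_integrity_error(self):
        with pytest.raises(IntegrityError):
            assign_short_read([(99, "A")], SNPS)

    def test_error_free_reads_recover_true_origin(self, clean_bundle):
        lookup = snp_lookup(discovered_snps(clean_bundle))
        assigned = assign_reads_frame(clean_bundle.short_reads, lookup)
        informative = assigned[assigned["covered"] >= 1]
        assert len(informative) > 1000
        assert (informative["call"] == informative["true_origin"]).all()

    def test_read_conservation(self, noisy_bundle):
        lookup = snp_lookup(discovered_snps(noisy_bundle))
        assigned = assign_reads_frame(noisy_bundle.short_reads, lookup)
        covering = assigned[assigned["covered"] >= 1]
        n_calls = (covering["call"] == BSB).sum() + (covering["call"] == TC).sum()
        n_amb = (covering["call"] == "ambiguous").sum()
        assert n_calls + n_amb == len(covering)


def counts_frame(rows):
    return pd.DataFrame(rows, columns=list(SNP_COUNT_COLUMNS))


class TestSnpAlleleCounts:
    def reads_frame(self, rows):
        return pd.DataFrame(
            rows,
            columns=[
                "read_id", "pair_id", "hybrid", "tissue", "replicate",
                "start", "end", "true_origin", "calls",
            ],
        )

    def test_simple_counting(self):
        lookup = {"p0": SNPS}
        rows = [
            (f"r{i}", "p0", "TBF3", "gonad", rep, 0, 100, BSB, "10:A")
            for i, rep in enumerate([1, 1, 1, 1, 1, 2, 3])
        ]
        rows += [
            (f"s{i}", "p0", "TBF3", "gonad", rep, 0, 100, TC, "10:G")
            for i, rep in enumerate([1, 1, 1, 2, 3])
        ]
        df = snp_allele_counts(self.reads_frame(rows), lookup)
        rep1 = df[(df["pos"] == 10) & (df["replicate"] == 1)]
        assert (rep1["bsb_reads"].iloc[0], rep1["tc_reads"].iloc[0]) == (5, 3)

    def test_snp_missing_in_one_replicate_dropped(self):
        lookup = {"p0": SNPS}
        rows = [
            ("r1", "p0", "TBF3", "gonad", 1, 0, 100, BSB, "10:A"),
            ("r2", "p0", "TBF3", "gonad", 3, 0, 100, BSB, "10:A"),
            # replicate 2 has no reads at SNP 10
            ("r3", "p0", "TBF3", "gonad", 2, 0, 100, BSB, "20:C"),
        ]
        df = snp_allele_counts(self.reads_frame(rows), lookup)
        assert 10 not in set(df["pos"])

    def test_totals_conserved_against_assignments(self, clean_bundle):
        lookup = snp_lookup(discovered_snps(clean_bundle))
        reads = clean_bundle.short_reads
        tissue = reads[reads["tissue"] == "gonad"]
        counts = snp_allele_counts(tissue, lookup)
        # every parental-allele count came from exactly one read-SNP
        # incidence; with error-free reads each read contributes its
        # covered-SNP count
        from homoeosplice.quant import parse_calls

        incidences = 0
        surviving = {
            (r.pair_id, r.pos, r.hybrid) for r in counts.itertuples()
        }
        for row in tissue.itertuples():
            for pos, _ in parse_calls(row.calls):
                if (row.pair_id, pos, row.hybrid) in surviving:
                    incidences += 1
        assert counts["bsb_reads"].sum() + counts["tc_reads"].sum() == incidences


class TestOutlierFilter:
    def test_across_replicates_mode_is_provably_vacuous(self):
        # with n=3 values the largest attainable |z| is 2/sqrt(3) < 2,
        # so the literal rule can never drop a cell, whatever the data
        rng = np.random.default_rng(0)
        rows = []
        for snp in range(40):
            for rep in (1, 2, 3):
                v = int(rng.integers(0, 10_000))
                rows.append(("p0", snp, "TBF3", "gonad", rep, v, 0))
        kept, dropped = filter_outlier_snps(
            counts_frame(rows), mode="across_replicates"
        )
        assert len(dropped) == 0
        assert len(kept) == 120

    def test_single_outlier_masked_below_eight_snps(self):
        # {10, 12, 11, 9, 120}: the inflated cell dominates the SD it is
        # judged against — max attainable z is (n-1)/sqrt(n) = 1.79 at n=5,
        # so mean±2SD cannot remove it; hand check: |120-32.4|/48.97 = 1.79
        values = {10: 10, 20: 12, 30: 11, 40: 9, 50: 120}
        rows = [
            ("p0", pos, "TBF3", "gonad", 1, v, 0) for pos, v in values.items()
        ]
        kept, dropped = filter_outlier_snps(counts_frame(rows))
        assert len(dropped) == 0
        assert set(kept["pos"]) == set(values)

    def test_hand_computed_within_gene_drop_at_eight_snps(self):
        # eight SNPs: mean 24.375, sample SD 38.65, |120-24.375| = 95.6 >
        # 2SD = 77.3 — the inflated cell is dropped, the others retained
        values = {10: 10, 20: 12, 30: 11, 40: 9, 50: 10, 60: 11, 70: 12, 80: 120}
        rows = [
            ("p0", pos, "TBF3", "gonad", 1, v, 0) for pos, v in values.items()
        ]
        kept, dropped = filter_outlier_snps(counts_frame(rows))
        assert list(dropped["pos"]) == [80]
        assert set(kept["pos"]) == set(values) - {80}

    def test_small_group_retained_with_warning(self, caplog):
        rows = [("p0", 10, "TBF3", "gonad", 1, 500, 0)]
        with caplog.at_level("WARNING"):
            kept, dropped = filter_outlier_snps(counts_frame(rows))
        assert len(kept) == 1 and len(dropped) == 0
        assert any("<2 values" in r.message for r in caplog.records)

    def test_filter_never_increases_counts(self):
        rng = np.random.default_rng(1)
        rows = [
            ("p0", pos, "TBF3", "gonad", rep, int(rng.poisson(20)), int(rng.poisson(20)))
            for pos in range(0, 200, 10)
            for rep in (1, 2, 3)
        ]
        df = counts_frame(rows)
        kept, _ = filter_outlier_snps(df)
        assert kept["bsb_reads"].sum() <= df["bsb_reads"].sum()
        assert kept["tc_reads"].sum() <= df["tc_reads"].sum()

    def test_planted_outliers_recovered_on_simulation(self):
        cfg = SimConfig(
            n_genes=20, seed=31, error_rate=0.0, het_snp_frac=0.0,
            outlier_snp_rate=0.05, outlier_inflation=10.0, depth=200.0,
        )
        bundle = generate_cohort(cfg)
        lookup = snp_lookup(discovered_snps(bundle))
        parts = [
            snp_allele_counts(
                bundle.short_reads[bundle.short_reads["tissue"] == t], lookup
            )
            for t in ("gonad", "liver", "muscle")
        ]
        counts = pd.concat(parts, ignore_index=True)
        kept, dropped = filter_outlier_snps(counts)
        planted = set(bundle.truth.outlier_cells)
        dropped_keys = {
            (r.pair_id, r.pos, r.hybrid, r.tissue, r.replicate)
            for r in dropped.itertuples()
        }
        snps_per_gene = counts.groupby("pair_id")["pos"].nunique()
        actionable = {
            p for p in planted if snps_per_gene.get(p[0], 0) >= 8
        }
        assert actionable, "expected planted outliers on well-powered genes"
        recovered = len(actionable & dropped_keys) / len(actionable)
        assert recovered >= 0.9
        # a mean±2SD cut inevitably clips ~4.6% of clean Poisson cells;
        # the false-removal rate must stay in that regime
        false_rate = len(dropped_keys - planted) / len(counts)
        assert false_rate <= 0.05


class TestGeneCounts:
    def test_sums_over_snps(self):
        rows = [
            ("p0", 10, "TBF3", "gonad", 1, 5, 3),
            ("p0", 20, "TBF3", "gonad", 1, 4, 2),
        ]
        matrix = gene_homoeolog_counts(counts_frame(rows))
        assert list(matrix[["bsb_count", "tc_count"]].iloc[0]) == [9, 5]

    def test_fully_filtered_gene_flagged_zero(self):
        rows = [("p1", 10, "TBF3", "gonad", 1, 5, 3)]
        matrix = gene_homoeolog_counts(counts_frame(rows), pairs=["p0", "p1"])
        p0 = matrix[matrix["pair_id"] == "p0"].iloc[0]
        assert (p0["bsb_count"], p0["tc_count"]) == (0, 0)
        assert bool(p0["no_snp_data"])

    def test_matrix_totals_match_snp_table(self, clean_bundle):
        lookup = snp_lookup(discovered_snps(clean_bundle))
        counts = pd.concat(
            [
                snp_allele_counts(
                    clean_bundle.short_reads[
                        clean_bundle.short_reads["tissue"] == t
                    ],
                    lookup,
                )
                for t in ("gonad", "liver", "muscle")
            ],
            ignore_index=True,
        )
        matrix = gene_homoeolog_counts(counts)
        assert matrix["bsb_count"].sum() == counts["bsb_reads"].sum()
        assert matrix["tc_count"].sum() == counts["tc_reads"].sum()


class TestNormalizeAndFilter:
    def matrix(self, rows):
        return pd.DataFrame(
            rows,
            columns=["pair_id", "hybrid", "tissue", "replicate",
                     "bsb_count", "tc_count"],
        )

    def test_cpm_arithmetic(self):
        rows = []
        # library of 2 million reads total; gene of interest contributes 4
        rows.append(("p0", "TBF3", "gonad", 1, 4, 0))
        rows.append(("p1", "TBF3", "gonad", 1, 1_999_996, 0))
        for rep in (2, 3):
            rows.append(("p0", "TBF3", "gonad", rep, 10, 10))
            rows.append(("p1", "TBF3", "gonad", rep, 10, 10))
        for rep in (1, 2, 3):
            rows.append(("p0", "BTF3", "gonad", rep, 10, 10))
            rows.append(("p1", "BTF3", "gonad", rep, 10, 10))
        norm, _ = normalize_and_filter(self.matrix(rows))
        cell = norm[
            (norm["pair_id"] == "p0")
            & (norm["hybrid"] == "TBF3")
            & (norm["replicate"] == 1)
        ]
        assert cell["bsb_cpm"].iloc[0] == pytest.approx(2.0)

    def test_cpm_sums_to_one_million_per_library(self, clean_bundle):
        lookup = snp_lookup(discovered_snps(clean_bundle))
        counts = pd.concat(
            [
                snp_allele_counts(
                    clean_bundle.short_reads[
                        clean_bundle.short_reads["tissue"] == t
                    ],
                    lookup,
                )
                for t in ("gonad", "liver", "muscle")
            ],
            ignore_index=True,
        )
        matrix = gene_homoeolog_counts(counts)
        norm, _ = normalize_and_filter(matrix)
        sums = norm.groupby(["hybrid", "tissue", "replicate"])[
            ["bsb_cpm", "tc_cpm"]
        ].sum().sum(axis=1)
        assert np.allclose(sums, 1e6, atol=1e-6)

    def test_min_count_boundary(self):
        rows = []
        for hybrid in ("TBF3", "BTF3"):
            for rep in (1, 2, 3):
                # p0: 5 in every replicate; p1: one replicate at 4
                rows.append(("p0", hybrid, "gonad", rep, 5, 5))
                p1 = 4 if (hybrid, rep) == ("BTF3", 3) else 5
                rows.append(("p1", hybrid, "gonad", rep, p1, 5))
        _, retained = normalize_and_filter(self.matrix(rows))
        assert retained[(BSB, "gonad")] == ["p0"]
        assert retained[(TC, "gonad")] == ["p0", "p1"]

    def test_zero_total_library_is_error(self):
        rows = [("p0", "TBF3", "gonad", 1, 0, 0)]
        with pytest.raises(StatisticsError):
            normalize_and_filter(self.matrix(rows))


class TestMitoOrigin:
    @pytest.mark.parametrize(
        "bsb,tc,expected",
        [
            (1000, 2, BSB),
            (2, 1000, TC),
            (60, 40, "undetermined"),
            (0, 0, "undetermined"),
            (95, 5, BSB),
            (94, 6, "undetermined"),
        ],
    )
    def test_threshold_calls(self, bsb, tc, expected):
        assert mito_origin_check(bsb, tc) == expected

    def test_synthetic_hybrids_match_maternal_truth(self, noisy_bundle):
        for hybrid, (b_count, t_count) in noisy_bundle.mito_counts.items():
            call = mito_origin_check(b_count, t_count)
            assert call == noisy_bundle.truth.maternal[hybrid]
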