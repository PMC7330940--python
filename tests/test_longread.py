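"""Full-length classification, 85%-concordance assignment, and exon-chain
AS-event classification."""

import numpy as np
import pytest

from homoeosplice import (
    SimConfig,
    assign_long_read,
    classify_as_events,
    classify_full_length,
    generate_cohort,
    high_as_genes,
    shared_as_across_homoeologs,
)
from homoeosplice.longread import shared_high_as_genes
from homoeosplice.quant import parse_calls, snp_lookup
from homoeosplice.snp_discovery import build_coordinate_map, call_species_snps
from homoeosplice.types import ASEvent, BSB, TC, ExonChain, InputShapeError, LongRead

from oracle_as import naive_classify, naive_pair_events, random_chain_pair


def chain(exons, strand="+", gene="g", cid=""):
    return ExonChain(gene, strand, tuple(exons), cid)


def read(length=500, f5=True, f3=True, polyA=True):
    return LongRead("r1", "g", length, f5, f3, polyA, chain([(0, length)]))


class TestFullLength:
    def test_length_boundary_is_strict(self):
        assert classify_full_length(read(length=301))
        assert not classify_full_length(read(length=300))

    @pytest.mark.parametrize("missing", ["f5", "f3", "polyA"])
    def test_any_missing_flag_fails(self, missing):
        assert not classify_full_length(read(**{missing: False}))

    def test_synthetic_fl_fraction_matches_truth_exactly(self, noisy_bundle):
        lr = noisy_bundle.long_reads
        calls = [
            classify_full_length(
                LongRead(
                    r.read_id, r.gene, r.length, r.has_5prime_primer,
                    r.has_3prime_primer, r.has_polyA, chain([(0, r.length)]),
                )
            )
            for r in lr.itertuples()
        ]
        truth = [noisy_bundle.truth.long_read_fl[r] for r in lr["read_id"]]
        assert calls == truth


SNPS = {i * 10: (frozenset("A"), frozenset("G")) for i in range(30)}


def calls_matching(n_bsb, n_tc):
    calls = [(i * 10, "A") for i in range(n_bsb)]
    calls += [((n_bsb + i) * 10, "G") for i in range(n_tc)]
    return calls


class TestAssignLongRead:
    def test_ninety_percent_assigned(self):
        assert assign_long_read(calls_matching(9, 1), SNPS) == BSB

    def test_eighty_percent_unassigned(self):
        assert assign_long_read(calls_matching(8, 2), SNPS) == "unassigned"

    def test_threshold_is_inclusive_at_85(self):
        assert assign_long_read(calls_matching(17, 3), SNPS) == BSB
        assert assign_long_read(calls_matching(16, 4), SNPS) == "unassigned"

    def test_tc_side(self):
        assert assign_long_read(calls_matching(0, 10), SNPS) == TC

    def test_no_covered_snps_has_reason_code(self):
        assert assign_long_read([], SNPS) == "unassigned:no_snp"

    def test_error_free_long_reads_recover_origin(self, clean_bundle):
        snps = []
        for pair_id, sub in clean_bundle.pileups.groupby("pair_id"):
            cmap = build_coordinate_map(pair_id, *clean_bundle.alignments[pair_id])
            snps.extend(call_species_snps(cmap, sub))
        lookup = snp_lookup(snps)
        n_checked = 0
        for row in clean_bundle.long_reads.itertuples():
            calls = parse_calls(row.calls)
            if not calls:
                continue
            got = assign_long_read(calls, lookup.get(row.pair_id, {}))
            assert got == row.true_origin
            n_checked += 1
        assert n_checked > 100


class TestClassifyPairwise:
    def test_identical_chains_yield_nothing(self):
        c = chain([(0, 100), (200, 300)])
        assert classify_as_events([c, c]) == []

    def test_skipped_exon(self):
        a = chain([(0, 100), (200, 300), (400, 500)], cid="a")
        b = chain([(0, 100), (400, 500)], cid="b")
        events = classify_as_events([a, b])
        assert [(e.type, e.anchor) for e in events] == [("SE", (200, 300))]
        assert set(events[0].support) == {"a", "b"}

    def test_retained_intron(self):
        a = chain([(0, 100), (200, 300)])
        b = chain([(0, 300)])
        events = classify_as_events([a, b])
        assert [(e.type, e.anchor) for e in events] == [("RI", (100, 200))]

    def test_alt_donor_plus_strand(self):
        a = chain([(0, 100), (200, 300)])
        b = chain([(0, 120), (200, 300)])
        events = classify_as_events([a, b])
        assert [(e.type, e.anchor) for e in events] == [
            ("A5SS", ((100, 120), 200))
        ]

    def test_alt_acceptor_plus_strand(self):
        a = chain([(0, 100), (200, 300)])
        b = chain([(0, 100), (180, 300)])
        events = classify_as_events([a, b])
        assert [(e.type, e.anchor) for e in events] == [
            ("A3SS", (100, (180, 200)))
        ]

    def test_mutually_exclusive_exons(self):
        a = chain([(0, 100), (200, 250), (400, 500)])
        b = chain([(0, 100), (300, 350), (400, 500)])
        events = classify_as_events([a, b])
        assert [(e.type, e.anchor) for e in events] == [
            ("MXE", ((200, 250), (300, 350)))
        ]

    def test_terminal_difference_is_ap(self):
        a = chain([(0, 100), (200, 300)])
        b = chain([(20, 100), (200, 300)])
        events = classify_as_events([a, b])
        assert [(e.type, e.anchor) for e in events] == [
            ("AP", ("start", (0, 20)))
        ]

    def test_unnamed_difference_falls_to_other(self):
        a = chain([(0, 100), (200, 300), (400, 500)])
        b = chain([(0, 100), (210, 320), (400, 500)])  # both edges moved
        events = classify_as_events([a, b])
        assert len(events) == 1
        assert events[0].type == "OTHER"

    def test_strand_flip_swaps_a5ss_a3ss_with_same_anchor(self):
        for exons_a, exons_b in [
            ([(0, 100), (200, 300)], [(0, 120), (200, 300)]),
            ([(0, 100), (200, 300)], [(0, 100), (180, 300)]),
        ]:
            plus = classify_as_events([chain(exons_a), chain(exons_b)])
            minus = classify_as_events(
                [chain(exons_a, strand="-"), chain(exons_b, strand="-")]
            )
            assert len(plus) == len(minus) == 1
            assert {plus[0].type, minus[0].type} == {"A5SS", "A3SS"}
            assert plus[0].anchor == minus[0].anchor

    def test_symmetry_in_chain_order(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            a, b = random_chain_pair(rng)
            ab = {(e.type, e.anchor) for e in classify_as_events([a, b])}
            ba = {(e.type, e.anchor) for e in classify_as_events([b, a])}
            assert ab == ba

    def test_completeness_distinct_chains_always_yield_events(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            a, b = random_chain_pair(rng)
            events = classify_as_events([a, b])
            if a.exons == b.exons:
                assert events == []
            else:
                assert len(events) >= 1

    def test_gene_mismatch_is_validation_error(self):
        a = ExonChain("g1", "+", ((0, 100),), "a")
        b = ExonChain("g2", "+", ((0, 100),), "b")
        with pytest.raises(InputShapeError, match="g2"):
            classify_as_events([a, b])

    def test_malformed_chain_rejected_at_construction(self):
        with pytest.raises(InputShapeError):
            ExonChain("g", "+", ((100, 50),))
        with pytest.raises(InputShapeError):
            ExonChain("g", "+", ((0, 100), (50, 150)))


class TestClassifierAgainstOracle:
    def test_random_pairs_match_naive_implementation(self):
        rng = np.random.default_rng(29)
        for _ in range(400):
            a, b = random_chain_pair(
                rng, strand="+" if rng.random() < 0.5 else "-"
            )
            got = {(e.type, e.anchor) for e in classify_as_events([a, b])}
            assert got == naive_pair_events(a, b)

    def test_random_three_chain_genes_match_naive_classifier(self):
        rng = np.random.default_rng(31)
        for _ in range(150):
            a, b = random_chain_pair(rng)
            _, c = random_chain_pair(rng)
            # re-key the third chain onto the same gene/strand
            c = ExonChain(a.gene, a.strand, c.exons, "c")
            chains = [a, b, c]
            got = {(e.type, e.anchor) for e in classify_as_events(chains)}
            assert got == naive_classify(chains)


class TestPlantedEventRecovery:
    def test_all_named_types_recovered_perfectly(self):
        cfg = SimConfig(
            n_genes=60, seed=41, error_rate=0.0, het_snp_frac=0.0,
            depth=20.0, exons_per_gene=(8, 14),
        )
        bundle = generate_cohort(cfg)
        truth_keys = set()
        per_type = {}
        for gene, events in bundle.truth.as_events.items():
            for ev in events:
                truth_keys.add(ev.key)
                per_type[ev.type] = per_type.get(ev.type, 0) + 1
        assert min(per_type.get(t, 0) for t in
                   ("SE", "RI", "A5SS", "A3SS", "MXE", "AP")) >= 30
        found_keys = set()
        for gene, chains in bundle.truth.chains.items():
            for ev in classify_as_events(chains):
                found_keys.add(ev.key)
        named_found = {k for k in found_keys if k[1] != "OTHER"}
        assert named_found == truth_keys  # precision = recall = 1


class TestSharedAndHighAS:
    def make_events(self, gene, homoeolog, keys):
        return [
            ASEvent(gene=gene, type=t, anchor=a, homoeolog=homoeolog)
            for t, a in keys
        ]

    def setup_map(self):
        return {"pair0": build_coordinate_map("pair0", "A" * 1000, "A" * 1000)}

    PAIRS = {"BSB_g0": "pair0", "TC_g0": "pair0"}

    def test_same_event_both_homoeologs_matches(self):
        maps = self.setup_map()
        ev_b = self.make_events("BSB_g0", BSB, [("SE", (200, 300))])
        ev_t = self.make_events("TC_g0", TC, [("SE", (200, 300))])
        matches = shared_as_across_homoeologs(ev_b, ev_t, maps, self.PAIRS)
        assert len(matches) == 1

    def test_same_coordinates_different_type_no_match(self):
        maps = self.setup_map()
        ev_b = self.make_events("BSB_g0", BSB, [("SE", (200, 300))])
        ev_t = self.make_events("TC_g0", TC, [("RI", (200, 300))])
        assert shared_as_across_homoeologs(ev_b, ev_t, maps, self.PAIRS) == []

    def test_unmapped_anchor_is_logged_not_matched(self, caplog):
        maps = {"pair0": build_coordinate_map("pair0", "AAAA", "AAAA")}
        ev_b = self.make_events("BSB_g0", BSB, [("SE", (200, 300))])
        ev_t = self.make_events("TC_g0", TC, [("SE", (200, 300))])
        with caplog.at_level("INFO"):
            matches = shared_as_across_homoeologs(ev_b, ev_t, maps, self.PAIRS)
        assert matches == []
        assert any("unmapped anchor" in r.message for r in caplog.records)

    def test_synthetic_shared_events_all_match(self, clean_bundle):
        bundle = clean_bundle
        maps = {
            pair: build_coordinate_map(pair, *aln)
            for pair, aln in bundle.alignments.items()
        }
        pair_of_gene = {}
        for pair_id, gid_b, gid_t in bundle.truth.ortholog_pairs:
            pair_of_gene[gid_b] = pair_id
            pair_of_gene[gid_t] = pair_id
        events_b, events_t = [], []
        n_shared_truth = 0
        for pair_id, gid_b, gid_t in bundle.truth.ortholog_pairs:
            events_b.extend(bundle.truth.as_events[gid_b])
            events_t.extend(bundle.truth.as_events[gid_t])
            if pair_id in bundle.truth.shared_as_pairs:
                n_shared_truth += len(bundle.truth.as_events[gid_b])
        matches = shared_as_across_homoeologs(
            events_b, events_t, maps, pair_of_gene
        )
        assert len(matches) == n_shared_truth

    def test_high_as_gene_boundary(self):
        four = self.make_events(
            "g1", BSB, [("SE", (i, i + 10)) for i in range(0, 40, 10)]
        )
        five = self.make_events(
            "g2", BSB, [("SE", (i, i + 10)) for i in range(0, 50, 10)]
        )
        assert high_as_genes(four + five) == ["g2"]

    def test_duplicate_events_not_double_counted(self):
        dup = self.make_events("g1", BSB, [("SE", (0, 10))] * 6)
        assert high_as_genes(dup) == []

    def test_intersection_across_lists(self):
        lists = [["g1", "g2", "g3"], ["g2", "g3"], ["g3", "g2", "g4"]]
        assert shared_high_as_genes(lists) == ["g2", "g3"]
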