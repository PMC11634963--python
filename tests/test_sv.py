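"""Breakend algebra, tolerance matching, consensus clustering, AR-GSR rules."""

import random

import pytest

from ctdnakit.panel import GenomicInterval
from ctdnakit.sv import (
    RETAINS_LEFT,
    RETAINS_RIGHT,
    Breakend,
    ConsensusSV,
    StructuralVariant,
    classify_lbd_truncating,
    consensus_merge,
    decompose_to_breakends,
    detect_ar_gsrs,
    filter_blacklist,
    flag_ecdna,
    infer_svtype,
    match_sv,
)


def sv(p1, p2, svtype=None, chrom1="chrX", chrom2=None, s1=RETAINS_LEFT, s2=RETAINS_RIGHT,
       sr=5, pe=5, caller="sv1"):
    chrom2 = chrom2 or chrom1
    b1, b2 = Breakend(chrom1, p1, s1), Breakend(chrom2, p2, s2)
    return StructuralVariant(b1, b2, svtype or infer_svtype(b1, b2), sr, pe, caller)


def consensus(svx, callers=("sv1", "sv2")):
    return ConsensusSV(svx, frozenset(callers), svx.split_reads, svx.discordant_reads)


class TestBreakendAlgebra:
    @pytest.mark.parametrize(
        "s1,s2,expected",
        [
            (RETAINS_LEFT, RETAINS_RIGHT, "DEL"),
            (RETAINS_RIGHT, RETAINS_LEFT, "DUP"),
            (RETAINS_LEFT, RETAINS_LEFT, "INV"),
            (RETAINS_RIGHT, RETAINS_RIGHT, "INV"),
        ],
    )
    def test_same_chromosome_orientation_table(self, s1, s2, expected):
        assert infer_svtype(Breakend("chr1", 100, s1), Breakend("chr1", 500, s2)) == expected
        # order of arguments must not matter
        assert infer_svtype(Breakend("chr1", 500, s2), Breakend("chr1", 100, s1)) == expected

    def test_cross_chromosome_is_translocation(self):
        for s1 in (RETAINS_LEFT, RETAINS_RIGHT):
            for s2 in (RETAINS_LEFT, RETAINS_RIGHT):
                assert infer_svtype(Breakend("chrX", 100, s1), Breakend("chr7", 500, s2)) == "TRA"

    @pytest.mark.parametrize("svtype", ["DEL", "DUP", "INV"])
    def test_decompose_round_trips(self, svtype):
        b1, b2 = decompose_to_breakends(svtype, "chr1", 100, 500)
        assert infer_svtype(b1, b2) == svtype

    def test_inversion_round_trips_for_both_layouts(self):
        for layout in (RETAINS_LEFT, RETAINS_RIGHT):
            b1, b2 = decompose_to_breakends("INV", "chr1", 100, 500, inv_layout=layout)
            assert infer_svtype(b1, b2) == "INV"

    def test_missing_end_is_an_error(self):
        from ctdnakit.sv import SvError
        with pytest.raises(SvError, match="END"):
            decompose_to_breakends("DEL", "chr1", 100, None)

    def test_length_is_breakend_difference_and_minus_one_for_tra(self):
        assert sv(100, 500).length == 400
        assert sv(100, 500, chrom2="chr7").length == -1


class TestMatching:
    def test_identical_svs_match(self):
        assert match_sv(sv(1000, 5000), sv(1000, 5000))

    @pytest.mark.parametrize("shift,expected", [(999, True), (1000, True), (1001, False)])
    def test_tolerance_boundary(self, shift, expected):
        assert match_sv(sv(1000, 5000), sv(1000 + shift, 5000 + shift)) is expected

    def test_one_breakend_out_of_tolerance_fails(self):
        assert not match_sv(sv(1000, 5000), sv(1000, 6200))

    def test_different_chromosomes_never_match(self):
        assert not match_sv(sv(1000, 5000, chrom1="chr1"), sv(1000, 5000, chrom1="chr2"))

    def test_symmetry(self):
        a, b = sv(1000, 5000), sv(1500, 5400)
        assert match_sv(a, b) == match_sv(b, a)


class TestConsensusMerge:
    def test_two_caller_cluster(self):
        sets = {
            "sv1": [sv(1000, 5000, caller="sv1")],
            "sv2": [],
            "sv3": [sv(1300, 4800, caller="sv3")],
            "sv4": [],
        }
        (merged,) = consensus_merge(sets)
        assert merged.supporting_callers == {"sv1", "sv3"}
        assert merged.representative.caller == "sv1"  # smallest caller ID wins

    def test_single_caller_cluster_retained_for_later_filtering(self):
        (merged,) = consensus_merge({"sv1": [sv(1000, 5000)], "sv2": [], "sv3": [], "sv4": []})
        assert merged.supporting_callers == {"sv1"}

    def test_read_support_is_per_field_maximum(self):
        sets = {
            "sv1": [sv(1000, 5000, sr=3, pe=9, caller="sv1")],
            "sv2": [sv(1100, 5100, sr=8, pe=2, caller="sv2")],
        }
        (merged,) = consensus_merge(sets)
        assert (merged.best_split_reads, merged.best_discordant_reads) == (8, 9)

    def test_permutation_invariance(self):
        rnd = random.Random(5)
        base = [sv(1000 * i, 1000 * i + 40000, caller=c)
                for i in range(1, 8) for c in ("sv1", "sv2", "sv3")]
        sets = {c: [s for s in base if s.caller == c] for c in ("sv1", "sv2", "sv3", "sv4")}
        out1 = consensus_merge(sets)
        shuffled = {c: rnd.sample(v, len(v)) for c, v in reversed(list(sets.items()))}
        out2 = consensus_merge(shuffled)
        assert out1 == out2

    def test_matches_connected_components_oracle(self):
        """Single-linkage merge equals brute-force union over an all-pairs match graph."""
        import networkx as nx

        rnd = random.Random(11)
        truth = [(rnd.randint(10_000, 90_000), rnd.randint(100_000, 200_000)) for _ in range(12)]
        sets = {c: [] for c in ("sv1", "sv2", "sv3", "sv4")}
        for p1, p2 in truth:
            for c in sets:
                if rnd.random() < 0.8:
                    j1, j2 = rnd.randint(-500, 500), rnd.randint(-500, 500)
                    sets[c].append(sv(p1 + j1, p2 + j2, caller=c))
        merged = consensus_merge(sets)

        flat = [s for c in sorted(sets) for s in sets[c]]
        g = nx.Graph()
        g.add_nodes_from(range(len(flat)))
        for i in range(len(flat)):
            for j in range(i + 1, len(flat)):
                if match_sv(flat[i], flat[j]):
                    g.add_edge(i, j)
        assert len(merged) == nx.number_connected_components(g)
        support = sorted(len(m.supporting_callers) for m in merged)
        oracle_support = sorted(
            len({flat[i].caller for i in comp}) for comp in nx.connected_components(g)
        )
        assert support == oracle_support


class TestBlacklist:
    BL = [GenomicInterval("chrX", 2000, 3000, "bl")]

    def test_breakend_inside_interval_removed(self):
        assert filter_blacklist([consensus(sv(2500, 9000))], self.BL) == []

    def test_breakends_outside_are_kept(self):
        kept = filter_blacklist([consensus(sv(1000, 9000))], self.BL)
        assert len(kept) == 1

    def test_half_open_boundaries(self):
        assert filter_blacklist([consensus(sv(3000, 9000))], self.BL) != []  # end excluded
        assert filter_blacklist([consensus(sv(2000, 9000))], self.BL) == []  # start included


class TestARGSRDetection:
    @pytest.mark.parametrize(
        "callers,sr,pe,expected",
        [
            (("sv1", "sv2"), 3, 3, 1),   # exactly at every threshold
            (("sv1", "sv2"), 5, 2, 0),   # both read thresholds required
            (("sv1", "sv2"), 2, 5, 0),
            (("sv1",), 10, 10, 0),       # single-caller support excluded
            (("sv1", "sv2", "sv3", "sv4"), 10, 10, 1),
        ],
    )
    def test_support_thresholds(self, ar, callers, sr, pe, expected):
        c = consensus(sv(1500, 4000, sr=sr, pe=pe), callers)
        assert len(detect_ar_gsrs([c], ar)) == expected

    def test_breakend_outside_ar_is_excluded(self, ar):
        c = consensus(sv(20_000, 60_000, sr=10, pe=10), ("sv1", "sv2", "sv3", "sv4"))
        assert detect_ar_gsrs([c], ar) == []

    def test_every_call_is_in_ar_region(self, ar):
        calls = detect_ar_gsrs(
            [consensus(sv(1500, 4000)), consensus(sv(8000, 12_000))], ar
        )
        assert calls and all(c.in_ar_region for c in calls)


class TestLBDRules:
    """Toy AR: exons at 1000+1000*i (600 bp), exon 8 = 8000-9000, stop 8900."""

    def test_del_over_lbd_exons_only_is_rule_1(self, ar):
        c = consensus(sv(4800, 7100, "DEL"))  # overlaps exons 5-7 only
        assert classify_lbd_truncating(c, ar) == 1

    def test_del_touching_exon_1_3_span_is_excluded(self, ar):
        c = consensus(sv(2500, 5500, "DEL"))  # spans exons 2-5 -> overlaps head
        assert classify_lbd_truncating(c, ar) is None

    def test_dup_covering_head_with_lbd_breakpoint_is_rule_2(self, ar):
        c = consensus(sv(900, 5000, "DUP", s1=RETAINS_RIGHT, s2=RETAINS_LEFT))
        assert classify_lbd_truncating(c, ar) == 2

    def test_internal_dup_flanking_lbd_exon_is_rule_3(self, ar):
        c = consensus(sv(3700, 6800, "DUP", s1=RETAINS_RIGHT, s2=RETAINS_LEFT))
        assert classify_lbd_truncating(c, ar) == 3

    def test_tra_keeping_centromeric_side_is_rule_4(self, ar):
        b1 = Breakend("chrX", 5000, RETAINS_LEFT)
        b2 = Breakend("chr7", 1_500_000, RETAINS_RIGHT)
        c = consensus(StructuralVariant(b1, b2, "TRA", 5, 5, "sv1"))
        assert classify_lbd_truncating(c, ar) == 4

    def test_tra_losing_centromeric_side_is_not_truncating(self, ar):
        b1 = Breakend("chrX", 5000, RETAINS_RIGHT)
        b2 = Breakend("chr7", 1_500_000, RETAINS_RIGHT)
        c = consensus(StructuralVariant(b1, b2, "TRA", 5, 5, "sv1"))
        assert classify_lbd_truncating(c, ar) is None

    def test_tra_breakpoint_outside_window_is_not_truncating(self, ar):
        b1 = Breakend("chrX", 2000, RETAINS_LEFT)  # before end of exon 3
        b2 = Breakend("chr7", 1_500_000, RETAINS_RIGHT)
        c = consensus(StructuralVariant(b1, b2, "TRA", 5, 5, "sv1"))
        assert classify_lbd_truncating(c, ar) is None


class TestEcdnaFlag:
    @pytest.mark.parametrize(
        "count,log2,expected",
        [(2, 0.5, True), (3, 2.0, True), (1, 2.0, False), (0, 2.0, False),
         (3, 0.3, False), (2, 0.2, False)],
    )
    def test_rule(self, count, log2, expected):
        assert flag_ecdna(count, log2) is expected


class TestVcfRoundTrip:
    def test_sv_vcf_round_trip(self, tmp_path):
        from ctdnakit.vcfio import read_sv_vcf, write_sv_vcf

        svs = [
            sv(1500, 4000, "DEL"),
            sv(2000, 6000, "DUP", s1=RETAINS_RIGHT, s2=RETAINS_LEFT),
            sv(3000, 7000, "INV", s1=RETAINS_LEFT, s2=RETAINS_LEFT),
            sv(5000, 1_500_000, chrom2="chr7"),
        ]
        path = tmp_path / "x.vcf"
        write_sv_vcf(svs, path)
        back = read_sv_vcf(path, "sv1")
        assert sorted(s.dedup_key for s in back) == sorted(s.dedup_key for s in svs)
        assert {s.svtype for s in back} == {"DEL", "DUP", "INV", "TRA"}

    def test_snv_vcf_round_trip(self, tmp_path):
        from ctdnakit.variants import RawVariantCall
        from ctdnakit.vcfio import read_snv_vcf, write_snv_vcf

        calls = [
            RawVariantCall("s1", "snvA", "chr17", 99, "A", "G", 0.125, 17),
            RawVariantCall("s1", "snvA", "chr13", 200, "CAA", "CA", 0.5, 30,
                           context="GGCAAAATT", context_start=196),
        ]
        path = tmp_path / "y.vcf"
        write_snv_vcf(calls, path)
        back = read_snv_vcf(path, "s1", "snvA")
        assert sorted(c.key for c in back) == sorted(c.key for c in calls)
        by_key = {c.key: c for c in back}
        k = ("chr13", 200, "CAA", "CA")
        assert by_key[k].context == "GGCAAAATT" and by_key[k].context_start == 196
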