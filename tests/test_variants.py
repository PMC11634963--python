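"""Variant normalization, two-caller consensus, pathogenicity filter, origin calls."""

import pytest

from ctdnakit.variants import (
    RawVariantCall,
    VariantAnnotation,
    apply_pathogenicity_filter,
    classify_origin,
    decompose_and_prefilter,
    intersect_callers,
    normalize_call,
    run_variant_filter,
)


def call(chrom="chr17", pos=99, ref="A", alt="G", vaf=0.1, alt_reads=20,
         caller="snvA", ctx="", ctx_start=-1, sid="s1"):
    return RawVariantCall(sid, caller, chrom, pos, ref, alt, vaf, alt_reads,
                         context=ctx, context_start=ctx_start)


class TestNormalization:
    def test_mnp_splits_into_per_base_snvs(self):
        out = normalize_call(call(pos=99, ref="AT", alt="GC"))
        assert [(c.pos, c.ref, c.alt) for c in out] == [(99, "A", "G"), (100, "T", "C")]
        assert all(c.vaf == 0.1 and c.alt_reads == 20 for c in out)

    def test_mnp_skips_matching_bases(self):
        out = normalize_call(call(ref="ATG", alt="GTG"))
        assert [(c.pos, c.ref, c.alt) for c in out] == [(99, "A", "G")]

    def test_prefix_trim(self):
        out = normalize_call(call(ref="CA", alt="CT"))
        assert [(c.pos, c.ref, c.alt) for c in out] == [(100, "A", "T")]

    def test_left_alignment_unifies_shifted_indels(self):
        """CAA>CA and the right-shifted AA>A reach the same normalized key.

        Oracle: applying either representation to the reference context yields
        the same haplotype string, so they denote the same edit.
        """
        ctx = "GGCAAAATT"  # context starting at pos 95
        a = call(pos=97, ref="CAA", alt="CA", ctx=ctx, ctx_start=95)
        b = call(pos=99, ref="AA", alt="A", ctx=ctx, ctx_start=95)

        def apply(v):
            off = v.pos - 95
            assert ctx[off:off + len(v.ref)] == v.ref
            return ctx[:off] + v.alt + ctx[off + len(v.ref):]

        assert apply(a) == apply(b)  # same edit by exhaustive string comparison
        (na,), (nb,) = normalize_call(a), normalize_call(b)
        assert na.key == nb.key
        assert apply(na) == apply(a)

    @pytest.mark.parametrize("alt_reads,kept", [(5, 0), (6, 1), (7, 1)])
    def test_min_alt_read_threshold(self, alt_reads, kept):
        out = decompose_and_prefilter([call(alt_reads=alt_reads)])
        assert len(out) == kept


class TestConsensus:
    def test_shared_key_is_retained_with_caller_a_values(self):
        a = [call(vaf=0.10, alt_reads=12, caller="snvA")]
        b = [call(vaf=0.55, alt_reads=40, caller="snvB")]
        (kept,) = intersect_callers(a, b)
        assert kept.vaf == 0.10 and kept.alt_reads == 12 and kept.caller == "snvA"

    def test_private_calls_are_dropped(self):
        a = [call(pos=99), call(pos=200)]
        b = [call(pos=99)]
        assert [c.pos for c in intersect_callers(a, b)] == [99]

    def test_consensus_is_subset_of_both_inputs(self):
        a = [call(pos=p) for p in (10, 20, 30)]
        b = [call(pos=p) for p in (20, 30, 40)]
        keys = {c.key for c in intersect_callers(a, b)}
        assert keys <= {c.key for c in a} and keys <= {c.key for c in b}

    def test_shifted_indel_intersects_after_normalization(self):
        ctx = "GGCAAAATT"
        a = decompose_and_prefilter([call(pos=97, ref="CAA", alt="CA", ctx=ctx, ctx_start=95)])
        b = decompose_and_prefilter([call(pos=99, ref="AA", alt="A", ctx=ctx, ctx_start=95)])
        assert len(intersect_callers(a, b)) == 1


def ann(gene="TP53", pchange="p.Arg175His", classes=("missense",), curated=True,
        onc="Oncogenic"):
    return VariantAnnotation(gene, pchange, frozenset(classes), curated, onc)


class TestPathogenicityFilter:
    @pytest.mark.parametrize(
        "annotation,keep,reason",
        [
            (ann(), True, None),
            (ann(curated=True, onc="Likely Oncogenic"), True, None),
            (ann(curated=True, onc="Other"), False, "not_oncogenic"),
            (ann(curated=False, onc=None), False, "not_oncogenic"),
            # uncurated oncogenic is kept unless it has a splice class
            (ann(curated=False, onc="Likely Oncogenic"), True, None),
            (ann(curated=False, onc="Likely Oncogenic", classes=("splice-region",)),
             False, "uncurated_splice"),
            (ann(curated=False, onc="Oncogenic", classes=("splice-site",)),
             False, "uncurated_splice"),
            # curated oncogenic splice variants survive
            (ann(curated=True, onc="Oncogenic", classes=("splice-site",)), True, None),
            # gene-specific removal ledger beats an oncogenic label
            (ann(gene="AURKA", pchange="p.Phe31Ile"), False, "gene_specific_ledger"),
            (ann(gene="ATM", pchange="p.His1380Tyr"), False, "gene_specific_ledger"),
            (ann(gene="FANCA", pchange="p.Ser858Arg"), False, "gene_specific_ledger"),
            # the misspelt symbol resolves to KMT2C before ledger lookup
            (ann(gene="KMTC2", pchange="p.Tyr816Ter"), False, "gene_specific_ledger"),
            (ann(gene="KMT2C", pchange="p.Tyr816Ter"), False, "gene_specific_ledger"),
            # FOXA1 ignores oncogenicity entirely
            (ann(gene="FOXA1", pchange="p.Met253Lys", curated=False, onc=None), True, None),
            (ann(gene="FOXA1", pchange="p.Gly87Gly", classes=("synonymous",)),
             False, "foxa1_synonymous"),
            (ann(gene="FOXA1", pchange="p.Ala83Thr"), False, "foxa1_listed_removal"),
            (ann(gene="FOXA1", pchange="p.Ser448Asn"), False, "foxa1_listed_removal"),
        ],
    )
    def test_filter_decisions(self, annotation, keep, reason):
        got_keep, got_reason = apply_pathogenicity_filter(annotation)
        assert (got_keep, got_reason) == (keep, reason)


class TestOriginClassification:
    @pytest.mark.parametrize(
        "gene,vaf,origin",
        [
            ("BRCA2", 0.50, "likely_germline"),
            ("BRCA2", 0.45, "likely_germline"),  # inclusive window edges
            ("BRCA2", 0.55, "likely_germline"),
            ("BRCA2", 0.96, "likely_germline"),
            ("BRCA2", 0.95, "likely_somatic"),   # strict > 0.95
            ("BRCA2", 0.20, "likely_somatic"),
            ("BRCA2", 0.449, "likely_somatic"),
            ("TP53", 0.50, "likely_somatic"),    # exempt genes stay somatic
            ("AR", 0.50, "likely_somatic"),
            ("PTEN", 0.97, "likely_somatic"),
            ("ERF", 0.50, "likely_somatic"),
            ("PIK3CA", 0.50, "likely_somatic"),
            ("CDK12", 0.50, "likely_somatic"),
            ("HSD3B1", 0.10, "likely_germline"),  # germline regardless of VAF
            ("HSD3B1", 0.50, "likely_germline"),
        ],
    )
    def test_origin(self, gene, vaf, origin):
        assert classify_origin(gene, vaf) == origin


class TestFilterPipeline:
    def _inputs(self):
        a = [
            call(pos=10, vaf=0.2, caller="snvA"),           # consensus, pathogenic
            call(pos=20, vaf=0.5, caller="snvA"),           # consensus, germline VAF band
            call(pos=30, caller="snvA"),                    # private to A
            call(pos=40, caller="snvA"),                    # consensus, benign
        ]
        b = [call(pos=p, caller="snvB") for p in (10, 20, 40, 50)]
        annotations = {
            ("chr17", 10, "A", "G"): ann(gene="TP53"),
            ("chr17", 20, "A", "G"): ann(gene="BRCA2"),
            ("chr17", 40, "A", "G"): ann(gene="SPOP", onc="Other"),
        }
        return a, b, annotations

    def test_kept_origins_and_audit_accounting(self):
        a, b, annotations = self._inputs()
        kept, audit = run_variant_filter(a, b, annotations)
        assert [(v.gene, v.origin) for v in kept] == [
            ("TP53", "likely_somatic"), ("BRCA2", "likely_germline"),
        ]
        # every dropped candidate carries exactly one reason; counts reconcile
        reasons = [e["reason"] for e in audit]
        assert reasons.count("not_in_both_callers") == 1
        assert reasons.count("not_oncogenic") == 1
        n_consensus = 3
        assert n_consensus - len(kept) == sum(
            1 for r in reasons if r != "not_in_both_callers"
        )

    def test_pipeline_is_idempotent(self):
        a, b, annotations = self._inputs()
        kept, _ = run_variant_filter(a, b, annotations)
        again = [
            RawVariantCall(v.sample_id, "snvA", v.chrom, v.pos, v.ref, v.alt, v.vaf, v.alt_reads)
            for v in kept
        ]
        again_b = [RawVariantCall(v.sample_id, "snvB", v.chrom, v.pos, v.ref, v.alt, v.vaf, v.alt_reads)
                   for v in kept]
        kept2, audit2 = run_variant_filter(again, again_b, annotations)
        assert [(v.key, v.origin) for v in kept2] == [(v.key, v.origin) for v in kept]
        assert audit2 == []
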