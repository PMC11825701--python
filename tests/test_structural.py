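"""Structural classification against the reference: categories, filters,
cryptic-exon detection, and agreement with the brute-force oracle."""

import numpy as np
import pytest

from oracles import oracle_category, oracle_cryptic_exons, random_query_models

from isoforge.model import GenomicInterval, TranscriptModel
from isoforge.structural import (
    CATEGORIES,
    FilterConfig,
    MissingSupportError,
    classify,
    classify_transcript,
    detect_intron_derived_exons,
    filter_models,
    reannotate,
)


def with_support(model, total):
    return TranscriptModel(
        model.transcript_id, model.gene_id, model.exons, {"s1": total}
    )


class TestCategories:
    def test_identical_chain_is_fsm_with_matched_id(self, small_reference):
        index = small_reference.index
        ref = small_reference.reference_model("G001")
        query = TranscriptModel("q", "", ref.exons)
        call = classify_transcript(query, index)
        assert call.category == "FSM"
        assert call.matched_reference_transcript == "G001.ref"
        assert call.novel_junctions == []

    def test_terminal_subchain_is_ism(self, small_reference):
        """Keeping only the last exons of a reference model is a contiguous
        sub-chain: the 5'-degraded isoform pattern."""
        index = small_reference.index
        ref = small_reference.reference_model("G001")
        query = TranscriptModel("q", "", ref.exons[-3:])
        call = classify_transcript(query, index)
        assert call.category == "ISM"
        # brute-force check: the chain occurs as a contiguous slice
        rj = ref.junctions
        qj = query.junctions
        assert any(rj[i : i + len(qj)] == qj for i in range(len(rj)))

    def test_non_contiguous_subchain_falls_to_nic(self, small_reference):
        index = small_reference.index
        ref = small_reference.reference_model("G001")
        exons = ref.exons[:2] + ref.exons[3:]  # skip an internal exon
        query = TranscriptModel("q", "", exons)
        assert classify_transcript(query, index).category == "NIC"

    def test_novel_splice_site_is_nnc(self, small_reference):
        index = small_reference.index
        ref = small_reference.reference_model("G001")
        exons = list(ref.exons)
        e = exons[2]
        exons[2] = GenomicInterval(e.chrom, e.start + 4, e.end, e.strand)
        query = TranscriptModel("q", "", tuple(exons))
        call = classify_transcript(query, index)
        assert call.category == "NNC"
        assert len(call.novel_splice_sites) >= 1

    def test_fsm_is_invariant_to_end_variation_within_terminal_exons(
        self, small_reference
    ):
        index = small_reference.index
        ref = small_reference.reference_model("G002")
        for d_start, d_end in ((-30, 0), (25, 0), (0, 30), (-15, -20)):
            exons = list(ref.exons)
            first, last = exons[0], exons[-1]
            exons[0] = GenomicInterval(
                first.chrom, first.start + d_start, first.end, first.strand
            )
            exons[-1] = GenomicInterval(
                last.chrom, last.start, last.end + d_end, last.strand
            )
            query = TranscriptModel("q", "", tuple(exons))
            assert classify_transcript(query, index).category == "FSM"

    def test_categories_partition_and_tally_sums(self, small_reference):
        index = small_reference.index
        models = random_query_models(small_reference, index, 120, seed=5)
        calls = classify(models, index)
        assert all(c.category in CATEGORIES for c in calls)
        tally = reannotate(calls)
        assert int(tally["count"].sum()) == len(models)
        assert set(tally["category"]) == set(CATEGORIES)

    def test_oracle_agreement_on_random_models(self, small_reference):
        index = small_reference.index
        models = random_query_models(small_reference, index, 250, seed=42)
        for m in models:
            assert classify_transcript(m, index).category == oracle_category(m, index)


class TestCrypticExons:
    def test_i14e_like_isoform_yields_one_strict_call(self, erbb2):
        call = classify_transcript(erbb2.isoform, erbb2.index)
        assert call.category == "NNC"
        assert len(call.novel_splice_sites) == 2
        calls = detect_intron_derived_exons(erbb2.isoform, call, erbb2.index)
        assert len(calls) == 1
        assert calls[0].host_intron_index == 14
        assert calls[0].mode == "strict"

    def test_exon_skip_isoform_has_no_cryptic_calls(self, small_reference):
        from isoforge.simulate import EventSpec, apply_event

        index = small_reference.index
        m, _ = apply_event(small_reference, "G003", EventSpec("exon_skip"))
        call = classify_transcript(m, index)
        assert detect_intron_derived_exons(m, call, index) == []

    def test_exon_straddling_a_boundary_is_excluded_in_both_modes(
        self, small_reference
    ):
        index = small_reference.index
        ref = small_reference.reference_model("G001")
        exons = list(ref.exons)
        mid = exons[2]
        # an internal exon that crosses the reference exon/intron boundary
        straddle = GenomicInterval(mid.chrom, mid.end - 10, mid.end + 40, mid.strand)
        query = TranscriptModel(
            "q", "", (exons[0], straddle, exons[-1])
        )
        call = classify_transcript(query, index)
        for mode in ("strict", "relaxed"):
            assert detect_intron_derived_exons(query, call, index, mode=mode) == []

    def test_strict_calls_are_a_subset_of_relaxed_calls(self, small_reference):
        from isoforge.simulate import EventSpec, apply_event

        index = small_reference.index
        m, _ = apply_event(small_reference, "G004", EventSpec("cryptic_exon"))
        call = classify_transcript(m, index)
        strict = detect_intron_derived_exons(m, call, index, "strict")
        relaxed = detect_intron_derived_exons(m, call, index, "relaxed")
        strict_keys = {(c.exon, c.host_transcript_id) for c in strict}
        relaxed_keys = {(c.exon, c.host_transcript_id) for c in relaxed}
        assert strict_keys <= relaxed_keys and strict

    def test_strict_calls_match_brute_force_containment_oracle(self, erbb2):
        call = classify_transcript(erbb2.isoform, erbb2.index)
        calls = detect_intron_derived_exons(erbb2.isoform, call, erbb2.index)
        expected = oracle_cryptic_exons(erbb2.isoform, "ERBB2L", erbb2.index)
        got = sorted(
            (c.exon.start, c.exon.end, c.host_transcript_id, c.host_intron_index)
            for c in calls
        )
        assert got == expected


class TestSupportFilter:
    def test_threshold_boundary_three_retained_two_dropped(self, small_reference):
        ref = small_reference.reference_model("G001")
        keep = with_support(ref, 3)
        drop = with_support(
            TranscriptModel("low", ref.gene_id, ref.exons), 2
        )
        retained, log = filter_models([keep, drop], FilterConfig(min_support=3))
        assert [m.transcript_id for m in retained] == [ref.transcript_id]
        assert log[0]["transcript_id"] == "low" and "2 < 3" in log[0]["reason"]

    def test_min_support_one_is_the_identity_on_supported_models(self, dataset):
        supported = [m for m in dataset.models]
        retained, log = filter_models(supported, FilterConfig(min_support=1))
        dropped_zero = [m for m in supported if m.total_support == 0]
        assert len(retained) == len(supported) - len(dropped_zero)

    def test_missing_support_names_the_transcript(self, small_reference):
        bare = small_reference.reference_model("G001")
        with pytest.raises(MissingSupportError, match="G001.ref"):
            filter_models([bare])

    def test_random_support_vectors_match_one_line_oracle(self, small_reference):
        rng = np.random.default_rng(0)
        ref = small_reference.reference_model("G001")
        models = [
            with_support(
                TranscriptModel(f"t{i}", ref.gene_id, ref.exons),
                int(rng.integers(0, 8)),
            )
            for i in range(1000)
        ]
        retained, _ = filter_models(models, FilterConfig(min_support=3))
        oracle = {m.transcript_id for m in models if sum(m.support.values()) >= 3}
        assert {m.transcript_id for m in retained} == oracle


class TestReannotate:
    def test_all_fsm_input_has_zero_novel(self, small_reference):
        index = small_reference.index
        models = [
            TranscriptModel(f"q{g}", "", small_reference.reference_model(g).exons)
            for g in small_reference.layouts
        ]
        calls = classify(models, index)
        reannotate(calls)
        assert all(c.novelty == "known" for c in calls)

    def test_planted_event_isoforms_are_all_novel_but_fsm_like_ones(self, dataset):
        calls = classify(
            [m for m in dataset.models if not m.transcript_id.endswith(".ref")],
            dataset.index,
        )
        reannotate(calls)
        truth_by_id = {t.transcript_id: t for t in dataset.truths}
        for c in calls:
            expected = "known" if truth_by_id[c.transcript_id].expected_category == "FSM" else "novel"
            assert c.novelty == expected
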