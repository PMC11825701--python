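"""ORF prediction, NMD features, translation, and the consequence cascade."""

import pytest
from hypothesis import given, settings, strategies as st

from isoforge.model import GenomicInterval, TranscriptModel, ValidationError
from isoforge.orf import (
    NmdConfig,
    classify_transcript_orf,
    find_orf,
    genomic_cds,
    nmd_features,
    translate,
)
from isoforge.simulate import EventSpec, SimConfig, apply_event, make_reference


def model(exon_coords, strand="+", tid="t1"):
    return TranscriptModel(
        tid, "g1",
        tuple(GenomicInterval("chr1", a, b, strand) for a, b in exon_coords),
    )


class TestFindOrf:
    def test_hand_built_poly_lysine_orf(self):
        """ATG + 90 A's + TAA inside UTRs: 32 codons including the stop,
        protein of 31 residues (M followed by 30 K)."""
        seq = "CCCCC" + "ATG" + "A" * 90 + "TAA" + "CCCCC"
        orf = find_orf(seq)
        assert orf is not None
        assert orf.cds_start == 5 and orf.cds_end == 5 + 96
        assert orf.length_aa == 31
        assert orf.protein == "M" + "K" * 30

    def test_sequence_without_atg_has_no_orf(self):
        assert find_orf("CCGGTTAACCGGTT" * 20) is None

    def test_equal_length_orfs_resolve_five_prime_most(self):
        block = "ATG" + "GCC" * 40 + "TAA"
        seq = "CC" + block + "CCCC" + block + "CC"
        orf = find_orf(seq)
        assert orf.cds_start == 2

    def test_below_minimum_length_returns_none(self):
        seq = "ATG" + "GCC" * 10 + "TAA"
        assert find_orf(seq, cfg=NmdConfig(min_orf_aa=30)) is None
        assert find_orf(seq, cfg=NmdConfig(min_orf_aa=5)) is not None

    def test_non_acgt_characters_are_rejected(self):
        with pytest.raises(ValidationError):
            find_orf("ATGNNNTAA")


class TestTranslate:
    def test_standard_code_examples(self):
        assert translate("ATGGCTTAA") == "MA"
        assert translate("ATGTGGAGC") == "MWS"

    def test_internal_stop_is_an_error(self):
        with pytest.raises(ValidationError):
            translate("ATGTAAGCCTAA")

    def test_cassette_contribution_is_34_residues_with_the_19mer(self, erbb2):
        iso_orf = find_orf(erbb2.isoform.spliced_sequence(erbb2.genome), "i")
        par_orf = find_orf(erbb2.parent.spliced_sequence(erbb2.genome), "p")
        assert iso_orf.length_aa - par_orf.length_aa == 34
        assert "SLPRIKLGGGPRGRGHRDW" in iso_orf.protein


class TestNmdFeatures:
    def make_two_exon(self, exon1_len, exon2_len):
        return model([(0, exon1_len), (exon1_len + 100, exon1_len + 100 + exon2_len)])

    def test_stop_far_upstream_of_last_junction_sets_ptc(self):
        """Stop 200 nt before the final junction: hand-computed from
        cumulative exon lengths (junction at 420 - 120 = 300, stop ends 100)."""
        m = self.make_two_exon(300, 120)
        seq = "C" + "ATG" + "GCC" * 31 + "TAA" + "C" * (420 - 100)
        orf = find_orf(seq, "t")
        assert orf.cds_end == 100
        feats = nmd_features(orf, m)
        assert feats.stop_to_last_junction == 300 - 100 == 200
        assert feats.ptc_flag

    def test_stop_in_final_exon_is_not_ptc(self):
        m = self.make_two_exon(90, 330)
        seq = "C" * 120 + "ATG" + "GCC" * 60 + "TAA" + "C" * (420 - 306)
        orf = find_orf(seq, "t")
        feats = nmd_features(orf, m)
        assert feats.stop_to_last_junction < 0 and not feats.ptc_flag

    def test_exactly_50_nt_is_not_ptc_rule_is_strict(self):
        m = self.make_two_exon(150, 120)
        # stop ends exactly 50 nt upstream of the junction at position 150
        seq = "C" * 4 + "ATG" + "GCC" * 30 + "TAA" + "C" * (270 - 100)
        orf = find_orf(seq, "t")
        assert orf.cds_end == 100
        feats = nmd_features(orf, m)
        assert feats.stop_to_last_junction == 50 and not feats.ptc_flag
        assert nmd_features(orf, m, NmdConfig(ptc_rule_nt=49)).ptc_flag

    def test_mono_exon_never_flags_ptc(self):
        m = model([(0, 300)])
        orf = find_orf("ATG" + "GCC" * 40 + "TAA" + "C" * (300 - 126), "t")
        feats = nmd_features(orf, m)
        assert feats.stop_to_last_junction is None and not feats.ptc_flag


class TestConsequenceCascade:
    def run_event(self, reference, gene, kind, params=None):
        m, truth = apply_event(reference, gene, EventSpec(kind, params or {}))
        genome = reference.genome_str()
        index = reference.index
        from isoforge.structural import classify_transcript

        call = classify_transcript(m, index)
        _, _, cons = classify_transcript_orf(
            m, gene, index, genome,
            matched_transcript=call.matched_reference_transcript,
        )
        return truth, cons

    @pytest.mark.parametrize(
        "kind,expected",
        [
            ("utr_only", "unchanged_ORF"),
            ("nagnag_shift", "NAGNAG"),
            ("alt_tes", "short_ORF"),
            ("ptc_insertion", "PTC_NMD"),
            ("cryptic_exon", "protein_coding_novel"),
        ],
    )
    def test_each_event_kind_maps_to_its_consequence(self, kind, expected):
        reference = make_reference(SimConfig(seed=23, n_genes=3, exons_per_gene=(8, 8)))
        truth, cons = self.run_event(reference, "G002", kind)
        assert truth.expected_orf_class == expected
        assert cons.consequence == expected

    def test_in_frame_cassette_adds_exactly_its_codons(self, erbb2):
        _, _, cons = classify_transcript_orf(
            erbb2.isoform, "ERBB2L", erbb2.index, erbb2.genome,
        )
        assert cons.consequence == "protein_coding_novel"

    def test_unchanged_orf_has_identical_genomic_cds(self, small_reference):
        m, _ = apply_event(small_reference, "G005", EventSpec("utr_only"))
        genome = small_reference.genome_str()
        parent = small_reference.reference_model("G005")
        orf_p = find_orf(parent.spliced_sequence(genome), "p")
        orf_n = find_orf(m.spliced_sequence(genome), "n")
        assert genomic_cds(parent, orf_p) == genomic_cds(m, orf_n)

    def test_classification_is_input_order_invariant(self):
        reference = make_reference(SimConfig(seed=31, n_genes=4))
        genome = reference.genome_str()
        index = reference.index
        events = []
        for gene, kind in (("G001", "cryptic_exon"), ("G002", "exon_skip"),
                           ("G003", "utr_only")):
            m, _ = apply_event(reference, gene, EventSpec(kind))
            events.append((m, gene))
        genome = reference.genome_str()
        forward = [
            classify_transcript_orf(m, g, index, genome)[2].consequence
            for m, g in events
        ]
        backward = [
            classify_transcript_orf(m, g, index, genome)[2].consequence
            for m, g in reversed(events)
        ]
        assert forward == backward[::-1]


@given(n_codons=st.integers(min_value=2, max_value=40))
@settings(max_examples=20, deadline=None)
def test_in_frame_insertion_grows_protein_by_length_over_three(n_codons):
    """Inserting L nt (L = 3k, stop-free in frame) lengthens the protein by
    exactly L/3 for a cassette planted in a fixture gene."""
    reference = make_reference(SimConfig(seed=13, n_genes=1, intron_len=(200, 260)))
    m, truth = apply_event(
        reference, "G001", EventSpec("cryptic_exon", {"length": 3 * n_codons}),
        seed=n_codons,
    )
    genome = reference.genome_str()
    parent = reference.reference_model("G001")
    orf_p = find_orf(parent.spliced_sequence(genome), "p")
    orf_n = find_orf(m.spliced_sequence(genome), "n")
    assert orf_n.length_aa - orf_p.length_aa == n_codons
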