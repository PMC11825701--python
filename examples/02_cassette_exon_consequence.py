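"""The intron-derived cassette exon worked example.

An ERBB2-like 27-exon gene carries a 102-nt cassette exon inside intron 14.
The derived isoform is classified NNC with one strict intron-derived exon
call; its ORF gains exactly 34 residues, including the 19-mer core of the
diagnostic immunogen peptide; a UGG-rich (ESRP-type) window sits at 47-60 bp
downstream of the cassette in the intron.
"""

from isoforge.event import scan_ugg_rich
from isoforge.orf import classify_transcript_orf, find_orf
from isoforge.simulate import make_erbb2_like_fixture
from isoforge.structural import classify_transcript, detect_intron_derived_exons

fx = make_erbb2_like_fixture()

parent_orf = find_orf(fx.parent.spliced_sequence(fx.genome), "parent")
iso_orf = find_orf(fx.isoform.spliced_sequence(fx.genome), "isoform")
print(f"parent ORF : {parent_orf.length_aa} aa")
print(f"isoform ORF: {iso_orf.length_aa} aa "
      f"(+{iso_orf.length_aa - parent_orf.length_aa} from the 102-nt cassette)")
print(f"19-mer immunogen core present: {fx.core_peptide in iso_orf.protein}")

call = classify_transcript(fx.isoform, fx.index)
cryptic = detect_intron_derived_exons(fx.isoform, call, fx.index)[0]
print(f"\nstructural category: {call.category}; "
      f"cassette hosted in intron {cryptic.host_intron_index} of "
      f"{cryptic.host_transcript_id}")

_, _, consequence = classify_transcript_orf(
    fx.isoform, "ERBB2L", fx.index, fx.genome
)
print(f"ORF consequence: {consequence.consequence}")

top = scan_ugg_rich(fx.downstream_intron_seq)[0]
print(f"\ntop UGG-rich window downstream of the cassette: "
      f"offsets {top.start_offset}-{top.end_offset} "
      f"({top.motif_count} UGG occurrences)")
# The window's position mirrors the splicing-enhancer region whose deletion
# abolishes cassette inclusion; offsets are 1-based from the first intronic
# base after the cassette's 3' end.
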