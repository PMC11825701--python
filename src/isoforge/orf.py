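"""ORF prediction, NMD feature computation, and ORF-consequence classes.

Each novel transcript is assigned exactly one of five consequence classes
relative to a reference ORF, with a fixed priority cascade:

1. ``unchanged_ORF``        — genomic CDS intervals identical to the reference
   (only UTRs changed).
2. ``NAGNAG``               — tandem-acceptor shift: same genomic stop codon
   and frame, junction chains differing at exactly one acceptor by 3 nt, and
   proteins related by a one-residue alteration at the N terminus.
3. ``short_ORF``            — no ORF, or predicted protein below the
   short-ORF threshold.
4. ``PTC_NMD``              — any NMD feature fires: a stop codon more than
   ``ptc_rule_nt`` (default 50) nt upstream of the last exon–exon junction,
   an over-long 3'UTR, or upstream ORFs in the 5'UTR.
5. ``protein_coding_novel`` — a plausibly productive novel protein.

Classes 1/2/5 form the coding major class, 3/4 the unproductive one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from Bio.Seq import Seq

from .model import (
    ConfigError,
    GenomicInterval,
    IsoforgeError,
    ReferenceIndex,
    TranscriptModel,
    ValidationError,
)

CONSEQUENCE_CLASSES = (
    "unchanged_ORF",
    "NAGNAG",
    "short_ORF",
    "PTC_NMD",
    "protein_coding_novel",
)

CODING_CLASSES = frozenset({"unchanged_ORF", "NAGNAG", "protein_coding_novel"})
UNPRODUCTIVE_CLASSES = frozenset({"short_ORF", "PTC_NMD"})

_STOPS = frozenset({"TAA", "TAG", "TGA"})


class NoReferenceOrfError(IsoforgeError):
    """No reference transcript of the gene yields an ORF to compare against."""


@dataclass(frozen=True)
class NmdConfig:
    ptc_rule_nt: int = 50
    short_orf_aa: int = 100
    long_utr3_nt: int = 350
    min_orf_aa: int = 30
    uorf_min_aa: int = 10

    def __post_init__(self) -> None:
        for name in ("ptc_rule_nt", "short_orf_aa", "long_utr3_nt", "min_orf_aa", "uorf_min_aa"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")


@dataclass(frozen=True)
class OrfRecord:
    """A predicted ORF in transcript coordinates (CDS includes the stop codon)."""

    transcript_id: str
    cds_start: int
    cds_end: int
    protein: str
    length_aa: int

    def __post_init__(self) -> None:
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ValidationError(
                f"{self.transcript_id}: CDS length not divisible by 3"
            )
        if self.protein and (not self.protein.startswith("M") or "*" in self.protein):
            raise ValidationError(
                f"{self.transcript_id}: protein must begin with M and contain "
                "no internal stop"
            )


@dataclass(frozen=True)
class NmdFeatures:
    stop_to_last_junction: Optional[int]  # nt; None for mono-exon
    ptc_flag: bool
    utr3_len: int
    long_utr3_flag: bool
    uorf_count: int


@dataclass
class OrfConsequence:
    transcript_id: str
    consequence: str  # one of CONSEQUENCE_CLASSES
    reference_orf_id: Optional[str]
    evidence: list[str] = field(default_factory=list)


def translate(cds_seq: str) -> str:
    """Standard-code translation of a CDS (stop codon excluded from protein)."""
    seq = cds_seq.upper()
    if len(seq) % 3 != 0:
        raise ValidationError("CDS length not divisible by 3")
    protein = str(Seq(seq).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise ValidationError("internal stop codon in CDS")
    return protein


def _orf_candidates(seq: str):
    """Yield (start, stop_end) for every ATG-initiated ORF with in-frame stop."""
    n = len(seq)
    # first in-frame stop after each position, per frame, via backward scan
    next_stop = [None] * 3
    stop_after: dict[int, Optional[int]] = {}
    for i in range(n - 3, -1, -1):
        frame = i % 3
        if seq[i : i + 3] in _STOPS:
            next_stop[frame] = i
        stop_after[i] = next_stop[frame]
    i = seq.find("ATG")
    while i != -1:
        stop = stop_after.get(i)
        if stop is not None and stop > i:
            yield i, stop + 3
        i = seq.find("ATG", i + 1)


def find_orf(
    seq: str, transcript_id: str = "", cfg: NmdConfig = NmdConfig()
) -> Optional[OrfRecord]:
    """Longest ATG-initiated ORF with an in-frame stop; ties break 5'-most.

    Returns None when no candidate reaches ``min_orf_aa`` residues.
    """
    seq = seq.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValidationError(
            f"{transcript_id or 'sequence'}: non-ACGT characters {sorted(bad)}"
        )
    best: Optional[tuple[int, int]] = None
    for start, end in _orf_candidates(seq):
        aa = (end - start) // 3 - 1
        if best is None or aa > (best[1] - best[0]) // 3 - 1:
            best = (start, end)
    if best is None:
        return None
    aa = (best[1] - best[0]) // 3 - 1
    if aa < cfg.min_orf_aa:
        return None
    protein = translate(seq[best[0] : best[1]])
    return OrfRecord(
        transcript_id=transcript_id,
        cds_start=best[0],
        cds_end=best[1],
        protein=protein,
        length_aa=aa,
    )


def nmd_features(
    orf: OrfRecord, model: TranscriptModel, cfg: NmdConfig = NmdConfig(), seq: Optional[str] = None
) -> NmdFeatures:
    """NMD-relevant features of an ORF in transcript space.

    ``stop_to_last_junction`` is measured from the base following the stop
    codon to the final exon–exon junction; the PTC flag applies the
    50-nt rule with strict inequality. ``seq`` (the transcript sequence) is
    needed to count upstream ORFs; without it the count is 0.
    """
    total = model.length
    if orf.cds_end > total:
        raise ValidationError(
            f"{orf.transcript_id}: ORF extends past transcript length"
        )
    if model.n_exons == 1:
        stop_to_last = None
        ptc = False
    else:
        last_exon_len = model.exon_lengths_transcript_order()[-1]
        last_junction_pos = total - last_exon_len
        stop_to_last = last_junction_pos - orf.cds_end
        ptc = stop_to_last > cfg.ptc_rule_nt
    utr3_len = total - orf.cds_end
    uorfs = 0
    if seq is not None:
        for start, end in _orf_candidates(seq.upper()[: orf.cds_start]):
            if (end - start) // 3 - 1 >= cfg.uorf_min_aa:
                uorfs += 1
    return NmdFeatures(
        stop_to_last_junction=stop_to_last,
        ptc_flag=ptc,
        utr3_len=utr3_len,
        long_utr3_flag=utr3_len > cfg.long_utr3_nt,
        uorf_count=uorfs,
    )


def genomic_cds(model: TranscriptModel, orf: OrfRecord) -> tuple[GenomicInterval, ...]:
    """Genomic intervals occupied by the CDS (including the stop codon)."""
    return tuple(model.transcript_to_genomic(orf.cds_start, orf.cds_end))


def _cds_genomic_stop_base(model: TranscriptModel, orf: OrfRecord) -> int:
    """Genomic coordinate of the final CDS base (last base of the stop codon)."""
    segs = model.transcript_to_genomic(orf.cds_end - 1, orf.cds_end)
    seg = segs[0]
    return seg.start if model.strand == "-" else seg.end - 1


def _nagnag_chain_shift(novel: TranscriptModel, ref: TranscriptModel) -> bool:
    """True when the chains differ at exactly one acceptor by exactly 3 nt."""
    a, b = novel.junctions, ref.junctions
    if len(a) != len(b) or novel.strand != ref.strand:
        return False
    diffs = [(x, y) for x, y in zip(a, b) if x != y]
    if len(diffs) != 1:
        return False
    (x, y) = diffs[0]
    if novel.strand == "+":
        same_donor = x[0] == y[0]
        shift = abs(x[1] - y[1])
    else:
        same_donor = x[1] == y[1]
        shift = abs(x[0] - y[0])
    return same_donor and shift == 3


def _nagnag_protein_relation(novel: str, ref: str) -> bool:
    """One-residue alteration at the N terminus, identical remainder."""
    if not novel or not ref or novel[0] != "M" or ref[0] != "M":
        return False
    if len(novel) == len(ref) + 1:
        return novel[2:] == ref[1:]
    if len(ref) == len(novel) + 1:
        return ref[2:] == novel[1:]
    if len(ref) == len(novel):
        return novel != ref and novel[1:] == ref[1:]
    return False


def resolve_reference_orf(
    gene_id: str,
    index: ReferenceIndex,
    genome: Mapping[str, str],
    cfg: NmdConfig = NmdConfig(),
    matched_transcript: Optional[str] = None,
) -> tuple[str, OrfRecord, TranscriptModel]:
    """Reference ORF for comparison: the matched transcript when available,
    otherwise the gene's longest-CDS transcript (ties: lexicographic id)."""
    candidates: Sequence[TranscriptModel]
    if matched_transcript is not None and matched_transcript in index.transcripts:
        candidates = [index.transcripts[matched_transcript]]
    else:
        candidates = index.genes.get(gene_id, [])
    best: Optional[tuple[str, OrfRecord, TranscriptModel]] = None
    for ref in sorted(candidates, key=lambda m: m.transcript_id):
        orf = find_orf(ref.spliced_sequence(genome), ref.transcript_id, cfg)
        if orf is None:
            continue
        if best is None or orf.length_aa > best[1].length_aa:
            best = (ref.transcript_id, orf, ref)
    if best is None:
        raise NoReferenceOrfError(
            f"gene {gene_id}: no reference transcript yields an ORF"
        )
    return best


def classify_consequence(
    model: TranscriptModel,
    orf: Optional[OrfRecord],
    nmd: Optional[NmdFeatures],
    ref_orf: OrfRecord,
    ref_model: TranscriptModel,
    cfg: NmdConfig = NmdConfig(),
) -> OrfConsequence:
    """Apply the five-class consequence cascade to one novel transcript."""
    out = OrfConsequence(
        transcript_id=model.transcript_id,
        consequence="",
        reference_orf_id=ref_orf.transcript_id,
    )
    ref_cds = genomic_cds(ref_model, ref_orf)
    if orf is not None:
        if genomic_cds(model, orf) == ref_cds:
            out.consequence = "unchanged_ORF"
            out.evidence.append("identical_genomic_CDS")
            return out
        if (
            _cds_genomic_stop_base(model, orf) == _cds_genomic_stop_base(ref_model, ref_orf)
            and _nagnag_chain_shift(model, ref_model)
            and _nagnag_protein_relation(orf.protein, ref_orf.protein)
        ):
            out.consequence = "NAGNAG"
            out.evidence.append("3nt_acceptor_shift")
            return out
    if orf is None or orf.length_aa < cfg.short_orf_aa:
        out.consequence = "short_ORF"
        out.evidence.append(
            "no_ORF" if orf is None else f"orf_{orf.length_aa}aa<{cfg.short_orf_aa}"
        )
        return out
    assert nmd is not None
    nmd_evidence = []
    if nmd.ptc_flag:
        nmd_evidence.append("PTC_50nt_rule")
    if nmd.long_utr3_flag:
        nmd_evidence.append("long_3UTR")
    if nmd.uorf_count > 0:
        nmd_evidence.append(f"uORF_x{nmd.uorf_count}")
    if nmd_evidence:
        out.consequence = "PTC_NMD"
        out.evidence.extend(nmd_evidence)
        return out
    out.consequence = "protein_coding_novel"
    out.evidence.append("productive_novel_CDS")
    return out


def classify_transcript_orf(
    model: TranscriptModel,
    gene_id: str,
    index: ReferenceIndex,
    genome: Mapping[str, str],
    cfg: NmdConfig = NmdConfig(),
    matched_transcript: Optional[str] = None,
) -> tuple[Optional[OrfRecord], Optional[NmdFeatures], OrfConsequence]:
    """Convenience wrapper: ORF + NMD features + consequence for one model."""
    seq = model.spliced_sequence(genome)
    orf = find_orf(seq, model.transcript_id, cfg)
    nmd = nmd_features(orf, model, cfg, seq=seq) if orf is not None else None
    ref_id, ref_orf, ref_model = resolve_reference_orf(
        gene_id, index, genome, cfg, matched_transcript=matched_transcript
    )
    consequence = classify_consequence(model, orf, nmd, ref_orf, ref_model, cfg)
    return orf, nmd, consequence
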