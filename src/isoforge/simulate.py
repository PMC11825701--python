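"""Synthetic genomes, annotations, isoform events, and junction counts.

The generator emulates the inputs of a long-read isoform study so that every
pipeline stage is testable without sequencing data: multi-exon coding genes
with canonical GT/AG introns, derived isoforms carrying exactly one planted
event each (with recorded truth labels), junction count tables drawn from a
Poisson/Binomial sampling model at known inclusion fraction psi, CAGE peaks
at annotated TSSs, and planted polyA motifs.

Design properties that make truth labels *exactly* recoverable:

* Exonic sequence outside planted start/stop codons is drawn from a T-free
  codon alphabet (A/C/G only). Since every stop codon and ATG contains a T,
  the planted ORF is the unique ATG-initiated ORF with an in-frame stop, in
  every reading frame — no spurious ORFs can outgrow it.
* Every exon length is a multiple of 3 and the start codon occupies the last
  3 nt of exon 2, so the reading frame has phase 0 at every junction; any
  in-frame cassette insertion therefore contributes whole codons.
* Gene architecture: exon 1 is pure 5'UTR; the CDS runs from the end of
  exon 2 to a stop codon in the final exon, leaving a 60-nt 3'UTR with a
  planted AATAAA; the intron upstream of exon 3 ends in CAGCAG (a tandem
  NAGNAG acceptor).

These are simulator conventions, not claims about real transcriptomes; see
the methods note for what they do and do not exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .event import EventDef
from .model import (
    ConfigError,
    GenomicInterval,
    IsoforgeError,
    JunctionCountTable,
    ReferenceIndex,
    SJRecord,
    TranscriptModel,
    reverse_complement,
)

EVENT_KINDS = (
    "exon_skip",
    "cryptic_exon",
    "intron_retention",
    "alt_tss",
    "alt_tes",
    "nagnag_shift",
    "utr_only",
    "ptc_insertion",
)

_TFREE_BASES = "ACG"
_TFREE_CODONS = tuple(
    a + b + c for a in _TFREE_BASES for b in _TFREE_BASES for c in _TFREE_BASES
)
_STOP_CODONS = ("TAA", "TAG", "TGA")
_UTR3_LEN = 60
_POLYA_MOTIF = "AATAAA"
_POLYA_OFFSET = 20  # nt from motif end to transcript 3' end

#: one common codon per residue; used for planted peptide cassettes
CODON_OF = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC", "G": "GGC",
    "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG", "M": "ATG", "N": "AAC",
    "P": "CCC", "Q": "CAG", "R": "CGC", "S": "AGC", "T": "ACC", "V": "GTG",
    "W": "TGG", "Y": "TAC",
}

IMMUNOGEN_PEPTIDE = "CSLPRIKLGGGPRGRGHRDW"  # conjugation Cys + 19-mer
CASSETTE_CORE_PEPTIDE = IMMUNOGEN_PEPTIDE[1:]  # the transcript-encoded 19-mer


class InfeasibleEventError(IsoforgeError):
    """The requested event cannot be planted in the chosen gene."""


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_genes: int = 12
    exons_per_gene: tuple[int, int] = (6, 9)
    exon_len: tuple[int, int] = (90, 180)
    intron_len: tuple[int, int] = (120, 260)
    samples: int = 6
    depth: float = 200.0  # expected junction-spanning reads per event per sample
    psi: Union[float, tuple[float, ...]] = 0.3
    pad: int = 200  # T-free flank on each side of a gene block
    gap: int = 120  # intergenic spacer between gene blocks
    cage_halfwidth: int = 10
    jitter_inclusion: bool = False

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.samples < 1:
            raise ConfigError("n_genes and samples must be positive")
        for name, (lo, hi) in (
            ("exons_per_gene", self.exons_per_gene),
            ("exon_len", self.exon_len),
            ("intron_len", self.intron_len),
        ):
            if lo <= 0 or hi < lo:
                raise ConfigError(f"invalid range for {name}: ({lo}, {hi})")
        if self.exons_per_gene[0] < 3:
            raise ConfigError("genes need at least 3 exons")
        if self.exon_len[0] < 90:
            raise ConfigError(
                "minimum exon length is 90 nt (last exon must hold the stop "
                f"codon plus a {_UTR3_LEN}-nt 3'UTR)"
            )
        if self.intron_len[0] < 30:
            raise ConfigError("minimum intron length is 30 nt")
        if self.depth <= 0:
            raise ConfigError("depth must be positive")
        for p in self.psi_per_sample():
            if not (0.0 <= p <= 1.0):
                raise ConfigError("psi must lie in [0, 1]")

    def psi_per_sample(self) -> tuple[float, ...]:
        if isinstance(self.psi, (int, float)):
            return tuple(float(self.psi) for _ in range(self.samples))
        psi = tuple(float(p) for p in self.psi)
        if len(psi) != self.samples:
            raise ConfigError("per-sample psi length must equal samples")
        return psi


@dataclass(frozen=True)
class EventSpec:
    kind: str
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ConfigError(f"unknown event kind {self.kind!r}")


@dataclass
class EventTruth:
    """Ground truth recorded when an event is planted."""

    transcript_id: str
    gene_id: str
    kind: str
    expected_category: str
    expected_orf_class: Optional[str]
    planted: dict = field(default_factory=dict)


@dataclass
class GeneLayout:
    """Sense-space layout of one simulated gene within its genomic block.

    Local coordinates run 5'->3' along the pre-mRNA (transcript orientation);
    the block maps to the genome forward strand directly (plus) or reverse-
    complemented (minus).
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    block_start: int
    block_len: int
    pad: int
    exons_local: list[tuple[int, int]]
    introns_local: list[tuple[int, int]]
    cds_start_t: int
    cds_end_t: int

    @property
    def n_exons(self) -> int:
        return len(self.exons_local)

    def local_to_genomic(self, a: int, b: int) -> GenomicInterval:
        if self.strand == "+":
            return GenomicInterval(
                self.chrom, self.block_start + a, self.block_start + b, "+"
            )
        return GenomicInterval(
            self.chrom,
            self.block_start + self.block_len - b,
            self.block_start + self.block_len - a,
            "-",
        )


class SimulatedReference:
    """A generated genome plus its annotation and per-gene layouts."""

    def __init__(self, genome: dict[str, bytearray], layouts: dict[str, GeneLayout]):
        self.genome = genome
        self.layouts = layouts

    def genome_str(self) -> dict[str, str]:
        return {c: seq.decode() for c, seq in self.genome.items()}

    def read_sense(self, layout: GeneLayout, a: int, b: int) -> str:
        chrom = self.genome[layout.chrom]
        if layout.strand == "+":
            return chrom[layout.block_start + a : layout.block_start + b].decode()
        g0 = layout.block_start + layout.block_len - b
        g1 = layout.block_start + layout.block_len - a
        return reverse_complement(chrom[g0:g1].decode())

    def write_sense(self, layout: GeneLayout, a: int, seq: str) -> None:
        chrom = self.genome[layout.chrom]
        if layout.strand == "+":
            g0 = layout.block_start + a
            chrom[g0 : g0 + len(seq)] = seq.encode()
        else:
            g1 = layout.block_start + layout.block_len - a
            chrom[g1 - len(seq) : g1] = reverse_complement(seq).encode()

    def model_from_local_exons(
        self,
        layout: GeneLayout,
        exons_local: Sequence[tuple[int, int]],
        transcript_id: str,
        support: Optional[Mapping[str, int]] = None,
    ) -> TranscriptModel:
        intervals = sorted(
            (layout.local_to_genomic(a, b) for a, b in exons_local),
            key=lambda iv: iv.start,
        )
        return TranscriptModel(
            transcript_id=transcript_id,
            gene_id=layout.gene_id,
            exons=tuple(intervals),
            support=dict(support) if support is not None else None,
        )

    def reference_model(self, gene_id: str) -> TranscriptModel:
        layout = self.layouts[gene_id]
        return self.model_from_local_exons(
            layout, layout.exons_local, layout.transcript_id
        )

    @property
    def index(self) -> ReferenceIndex:
        return ReferenceIndex(
            {g: [self.reference_model(g)] for g in sorted(self.layouts)}
        )

    def cage_peaks(self, halfwidth: int = 10) -> list[GenomicInterval]:
        peaks = []
        for gene_id in sorted(self.layouts):
            m = self.reference_model(gene_id)
            peaks.append(
                GenomicInterval(
                    m.chrom,
                    max(0, m.tss - halfwidth),
                    m.tss + halfwidth + 1,
                    m.strand,
                )
            )
        return peaks


def _tfree(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_TFREE_BASES), size=n)) if n > 0 else ""


def _tfree_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_TFREE_CODONS), size=n)) if n > 0 else ""


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n)) if n > 0 else ""


def _round3(x: int) -> int:
    return x - (x % 3)


def _build_gene(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    strand: str,
    block_start: int,
    exon_lengths: Sequence[int],
    intron_lengths: Sequence[int],
    pad: int,
    intron_overrides: Optional[Mapping[int, str]] = None,
) -> tuple[str, GeneLayout]:
    """Assemble one gene's sense-space block sequence and layout."""
    n = len(exon_lengths)
    if n < 3:
        raise ConfigError(f"{gene_id}: need >= 3 exons")
    if any(e % 3 != 0 for e in exon_lengths):
        raise ConfigError(f"{gene_id}: exon lengths must be multiples of 3")
    if exon_lengths[-1] < _UTR3_LEN + 30:
        raise ConfigError(f"{gene_id}: last exon too short for stop + 3'UTR")
    overrides = dict(intron_overrides or {})

    total_exonic = sum(exon_lengths)
    cds_start_t = exon_lengths[0] + exon_lengths[1] - 3
    cds_end_t = total_exonic - _UTR3_LEN
    n_body_codons = (cds_end_t - cds_start_t - 6) // 3

    utr5 = _tfree(rng, cds_start_t)
    stop = str(rng.choice(list(_STOP_CODONS)))
    cds = "ATG" + _tfree_codons(rng, n_body_codons) + stop
    utr3 = list(_tfree(rng, _UTR3_LEN))
    motif_start = _UTR3_LEN - _POLYA_OFFSET - len(_POLYA_MOTIF)
    utr3[motif_start : motif_start + len(_POLYA_MOTIF)] = list(_POLYA_MOTIF)
    mrna = utr5 + cds + "".join(utr3)
    assert len(mrna) == total_exonic

    introns: list[str] = []
    for k, ilen in enumerate(intron_lengths, start=1):
        if k in overrides:
            seq = overrides[k]
            if len(seq) != ilen:
                raise ConfigError(
                    f"{gene_id}: intron {k} override length {len(seq)} != {ilen}"
                )
        else:
            body = list(_random_dna(rng, ilen - 4))
            seq = "GT" + "".join(body) + "AG"
            if k == 2:
                # tandem acceptor for NAGNAG events
                seq = seq[:-6] + "CAGCAG"
        if not (seq.startswith("GT") and seq.endswith("AG")):
            raise ConfigError(f"{gene_id}: intron {k} lacks canonical GT/AG")
        introns.append(seq)

    parts = [_tfree(rng, pad)]
    exons_local: list[tuple[int, int]] = []
    introns_local: list[tuple[int, int]] = []
    pos = pad
    offset = 0
    for i, elen in enumerate(exon_lengths):
        parts.append(mrna[offset : offset + elen])
        exons_local.append((pos, pos + elen))
        pos += elen
        offset += elen
        if i < n - 1:
            parts.append(introns[i])
            introns_local.append((pos, pos + len(introns[i])))
            pos += len(introns[i])
    parts.append(_tfree(rng, pad))
    block = "".join(parts)
    layout = GeneLayout(
        gene_id=gene_id,
        transcript_id=f"{gene_id}.ref",
        chrom=chrom,
        strand=strand,
        block_start=block_start,
        block_len=len(block),
        pad=pad,
        exons_local=exons_local,
        introns_local=introns_local,
        cds_start_t=cds_start_t,
        cds_end_t=cds_end_t,
    )
    return block, layout


def make_reference(config: SimConfig = SimConfig()) -> SimulatedReference:
    """Generate a genome and annotation; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    chrom = "chr1"
    pieces: list[str] = []
    layouts: dict[str, GeneLayout] = {}
    cursor = 0
    for g in range(config.n_genes):
        gene_id = f"G{g + 1:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lengths = [
            max(90, _round3(int(rng.integers(config.exon_len[0], config.exon_len[1] + 1))))
            for _ in range(n_ex)
        ]
        intron_lengths = [
            int(rng.integers(config.intron_len[0], config.intron_len[1] + 1))
            for _ in range(n_ex - 1)
        ]
        block, layout = _build_gene(
            rng, gene_id, chrom, strand, cursor, exon_lengths, intron_lengths,
            config.pad,
        )
        if strand == "-":
            block = reverse_complement(block)
        pieces.append(block)
        layouts[gene_id] = layout
        cursor += len(block)
        spacer = _random_dna(rng, config.gap)
        pieces.append(spacer)
        cursor += len(spacer)
    genome = {chrom: bytearray("".join(pieces).encode())}
    return SimulatedReference(genome, layouts)


# ---------------------------------------------------------------------------
# Event planting
# ---------------------------------------------------------------------------

def _transcript_pos(exons_local: Sequence[tuple[int, int]], local: int) -> int:
    """Transcript-space coordinate of a sense-local position."""
    t = 0
    for a, b in exons_local:
        if a <= local <= b:
            return t + (local - a)
        t += b - a
    raise ValueError(f"local position {local} not exonic")


def _cds_internal_introns(layout) -> list[int]:
    """1-based intron indices whose junction falls inside the CDS."""
    out = []
    for k in range(1, layout.n_exons):
        junction_t = _transcript_pos(layout.exons_local, layout.exons_local[k - 1][1])
        if layout.cds_start_t < junction_t < layout.cds_end_t - 3:
            out.append(k)
    return out


def _apply_cryptic_exon(ref, layout, rng, params, truth):
    length = int(params.get("length", 99))
    if length < 6 or length % 3 != 0:
        raise InfeasibleEventError("cassette length must be >= 6 and a multiple of 3")
    if "host_intron" in params:
        k = int(params["host_intron"])
    else:
        internal = _cds_internal_introns(layout)
        if not internal:
            raise InfeasibleEventError("no CDS-internal intron")
        k = max(
            internal,
            key=lambda i: layout.introns_local[i - 1][1] - layout.introns_local[i - 1][0],
        )
    if not (1 <= k <= layout.n_exons - 1):
        raise InfeasibleEventError(f"no intron {k}")
    junction_t = _transcript_pos(layout.exons_local, layout.exons_local[k - 1][1])
    if not (layout.cds_start_t < junction_t < layout.cds_end_t - 3):
        raise InfeasibleEventError(f"intron {k} not inside the CDS")
    i0, i1 = layout.introns_local[k - 1]
    offset = int(params.get("offset", 12))
    cassette = params.get("cassette_seq")
    if cassette is None:
        cassette = _tfree_codons(rng, length // 3)
    else:
        cassette = str(cassette)
        length = len(cassette)
    downstream = params.get("downstream_override")
    tail_needed = len(downstream) if downstream is not None else 14
    if offset < 8 or (i1 - i0) < offset + length + tail_needed:
        raise InfeasibleEventError(
            f"intron {k} too short for a {length}-nt cassette"
        )
    a = i0 + offset
    ref.write_sense(layout, a - 2, "AG")
    ref.write_sense(layout, a, cassette)
    if downstream is not None:
        if i0 + offset + length + len(downstream) != i1:
            raise InfeasibleEventError("downstream override must reach the intron end")
        if not (downstream.startswith("GT") and downstream.endswith("AG")):
            raise InfeasibleEventError("downstream override must keep GT...AG")
        ref.write_sense(layout, a + length, downstream)
    elif params.get("plant_ugg") and i1 - (a + length) >= 64:
        # donor + TGG-free spacer + UGG-rich window at downstream offsets 47-60
        seg = "GT" + "AC" * 22 + "GGTGGTGGTGGTGG"
        ref.write_sense(layout, a + length, seg)
        truth.planted["ugg_window"] = (47, 60)
    else:
        ref.write_sense(layout, a + length, "GT")
    exons = list(layout.exons_local)
    exons.insert(k, (a, a + length))
    truth.expected_category = "NNC"
    truth.expected_orf_class = "protein_coding_novel"
    truth.planted.update(
        {
            "host_intron_index": k,
            "cassette_local": (a, a + length),
            "cassette_genomic": layout.local_to_genomic(a, a + length),
            "cassette_len": length,
            "added_aa": length // 3,
        }
    )
    return exons


def _apply_exon_skip(ref, layout, rng, params, truth):
    n = layout.n_exons
    candidates = [int(params["exon"])] if "exon" in params else list(range(3, n))
    for k in candidates:
        if not (3 <= k <= n - 1):
            continue
        a, b = layout.exons_local[k - 1]
        remaining_aa = (layout.cds_end_t - layout.cds_start_t - (b - a)) // 3 - 1
        if remaining_aa >= 100:
            exons = [e for i, e in enumerate(layout.exons_local, start=1) if i != k]
            truth.expected_category = "NIC"
            truth.expected_orf_class = "protein_coding_novel"
            truth.planted.update({"skipped_exon": k, "removed_aa": (b - a) // 3})
            return exons
    raise InfeasibleEventError("no skippable in-frame CDS exon leaves >=100 aa")


def _apply_intron_retention(ref, layout, rng, params, truth):
    n = layout.n_exons
    candidates = (
        [int(params["intron"])] if "intron" in params else list(range(n - 2, 1, -1))
    )
    total = sum(b - a for a, b in layout.exons_local)
    for k in candidates:
        if not (2 <= k <= n - 2):
            continue
        i0, i1 = layout.introns_local[k - 1]
        intron_seq = ref.read_sense(layout, i0, i1)
        junction_t = _transcript_pos(layout.exons_local, layout.exons_local[k - 1][1])
        if junction_t <= layout.cds_start_t:
            continue
        stop_off = None
        for j in range(0, len(intron_seq) - 2, 3):
            if intron_seq[j : j + 3] in _STOP_CODONS:
                stop_off = j
                break
        if stop_off is None:
            continue
        prefix_nt = junction_t - layout.cds_start_t + stop_off + 3
        prefix_aa = prefix_nt // 3 - 1
        total_new = total + len(intron_seq)
        last_exon_len = layout.exons_local[-1][1] - layout.exons_local[-1][0]
        stop_end = junction_t + stop_off + 3
        distance = (total_new - last_exon_len) - stop_end
        if prefix_aa < 100 or prefix_nt <= len(intron_seq) or distance <= 50:
            continue
        exons = list(layout.exons_local)
        merged = (exons[k - 1][0], exons[k][1])
        exons = exons[: k - 1] + [merged] + exons[k + 1 :]
        truth.expected_category = "NIC"
        truth.expected_orf_class = "PTC_NMD"
        truth.planted.update(
            {"retained_intron": k, "ptc_to_last_junction_nt": distance}
        )
        return exons
    raise InfeasibleEventError("no retainable intron yields a guaranteed PTC")


def _apply_alt_tss(ref, layout, rng, params, truth):
    if layout.n_exons < 3:
        raise InfeasibleEventError("alt_tss needs >= 3 exons")
    exons = list(layout.exons_local[1:])
    truth.expected_category = "ISM"
    truth.expected_orf_class = "unchanged_ORF"
    truth.planted.update({"dropped_first_exons": 1})
    return exons


def _apply_alt_tes(ref, layout, rng, params, truth):
    if layout.n_exons < 3:
        raise InfeasibleEventError("alt_tes needs >= 3 exons")
    trim = int(params.get("trim", 6))
    a, b = layout.exons_local[1]
    if b - trim <= a:
        raise InfeasibleEventError("trim exceeds exon 2")
    exons = [layout.exons_local[0], (a, b - trim)]
    truth.expected_category = "ISM"
    truth.expected_orf_class = "short_ORF"
    truth.planted.update({"kept_exons": 2, "trim": trim})
    return exons


def _apply_nagnag(ref, layout, rng, params, truth):
    if layout.n_exons < 3:
        raise InfeasibleEventError("nagnag_shift needs >= 3 exons")
    i0, i1 = layout.introns_local[1]
    tail = ref.read_sense(layout, i1 - 6, i1)
    if tail != "CAGCAG":
        raise InfeasibleEventError("intron 2 lacks the tandem CAGCAG acceptor")
    exons = list(layout.exons_local)
    a, b = exons[2]
    exons[2] = (a - 3, b)
    truth.expected_category = "NNC"
    truth.expected_orf_class = "NAGNAG"
    truth.planted.update({"shifted_acceptor_exon": 3, "shift_nt": 3})
    return exons


def _apply_utr_only(ref, layout, rng, params, truth):
    extend = int(params.get("extend", 50))
    a, b = layout.exons_local[0]
    if a - extend < 0:
        raise InfeasibleEventError("upstream pad too small for the extension")
    exons = [(a - extend, b)] + list(layout.exons_local[1:])
    truth.expected_category = "FSM"
    truth.expected_orf_class = "unchanged_ORF"
    truth.planted.update({"utr5_extension": extend})
    return exons


def _apply_ptc_insertion(ref, layout, rng, params, truth):
    n = layout.n_exons
    candidates = [int(params["exon"])] if "exon" in params else [n - 2]
    total = sum(b - a for a, b in layout.exons_local)
    for k in candidates:
        if not (3 <= k <= n - 2):
            continue
        i0, i1 = layout.introns_local[k - 1]
        if i1 - i0 < 12:
            continue
        junction_t = _transcript_pos(layout.exons_local, layout.exons_local[k - 1][1])
        prefix_aa = (junction_t - layout.cds_start_t) // 3 + 1  # + the Val codon
        mid_lens = [
            b - a for a, b in layout.exons_local[k : n - 1]
        ]  # exons k+1 .. n-1
        distance = sum(mid_lens)
        if prefix_aa < 100 or distance <= 50:
            continue
        # extension reads GTA TAA: intron bases 0..6 become exonic, the new
        # donor needs GT at offset 6; parent intron keeps its GT start.
        ref.write_sense(layout, i0 + 2, "ATAAGT")
        exons = list(layout.exons_local)
        a, b = exons[k - 1]
        exons[k - 1] = (a, b + 6)
        truth.expected_category = "NNC"
        truth.expected_orf_class = "PTC_NMD"
        truth.planted.update(
            {"extended_exon": k, "ptc_to_last_junction_nt": distance}
        )
        return exons
    raise InfeasibleEventError("no exon admits a PTC-bearing extension")


_EVENT_BUILDERS = {
    "cryptic_exon": _apply_cryptic_exon,
    "exon_skip": _apply_exon_skip,
    "intron_retention": _apply_intron_retention,
    "alt_tss": _apply_alt_tss,
    "alt_tes": _apply_alt_tes,
    "nagnag_shift": _apply_nagnag,
    "utr_only": _apply_utr_only,
    "ptc_insertion": _apply_ptc_insertion,
}


def apply_event(
    reference: SimulatedReference,
    gene_id: str,
    event: EventSpec,
    seed: int = 0,
    transcript_id: Optional[str] = None,
) -> tuple[TranscriptModel, EventTruth]:
    """Derive a novel isoform from a gene's reference transcript.

    The returned model differs from its parent by exactly the requested
    event; the truth record carries the expected structural category, the
    expected ORF-consequence class (None when not determined by
    construction), and all planted coordinates. Infeasible events raise
    :class:`InfeasibleEventError` — never silent truncation.
    """
    if gene_id not in reference.layouts:
        raise ConfigError(f"unknown gene {gene_id!r}")
    layout = reference.layouts[gene_id]
    rng = np.random.default_rng(seed)
    tid = transcript_id or f"{gene_id}.{event.kind}"
    truth = EventTruth(
        transcript_id=tid,
        gene_id=gene_id,
        kind=event.kind,
        expected_category="",
        expected_orf_class=None,
    )
    exons_local = _EVENT_BUILDERS[event.kind](
        reference, layout, rng, dict(event.params), truth
    )
    model = reference.model_from_local_exons(layout, exons_local, tid)
    truth.planted.setdefault("exons_local", list(exons_local))
    return model, truth


# ---------------------------------------------------------------------------
# Junction-count simulation
# ---------------------------------------------------------------------------

def simulate_junction_counts(
    event: EventDef,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[JunctionCountTable]:
    """Per-sample junction tables under the Poisson/Binomial inclusion model.

    For each sample: N ~ Poisson(depth) junction-spanning read pairs;
    I ~ Binomial(N, psi) support the cassette. Both inclusion junctions
    receive the identical count I (a read pair spanning the cassette spans
    both junctions) unless ``jitter_inclusion`` is set; the exclusion
    junction receives N - I.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    psi = config.psi_per_sample()
    strand = event.strand
    tables = []
    for s in range(config.samples):
        n = int(rng.poisson(config.depth))
        inc = int(rng.binomial(n, psi[s])) if n > 0 else 0
        inc_down = (
            int(rng.binomial(n, psi[s])) if (config.jitter_inclusion and n > 0) else inc
        )
        exc = n - inc
        table = JunctionCountTable(sample_id=f"S{s + 1:02d}")
        for junction, count, annotated in (
            (event.inclusion_up, inc, False),
            (event.inclusion_down, inc_down, False),
            (event.exclusion, exc, True),
        ):
            table.add(
                SJRecord(
                    chrom=event.chrom,
                    start=junction[0],
                    end=junction[1],
                    strand=strand,
                    motif=1,
                    annotated=annotated,
                    unique_reads=count,
                    multi_reads=0,
                    max_overhang=50,
                )
            )
        tables.append(table)
    return tables


def event_def_from_truth(truth: EventTruth, reference: SimulatedReference) -> EventDef:
    """The three-junction event definition of a planted cryptic exon."""
    if truth.kind != "cryptic_exon":
        raise ConfigError("event definitions require a cryptic_exon truth record")
    layout = reference.layouts[truth.gene_id]
    k = truth.planted["host_intron_index"]
    i0, i1 = layout.introns_local[k - 1]
    intron = layout.local_to_genomic(i0, i1)
    cassette = truth.planted["cassette_genomic"]
    return EventDef(
        name=truth.transcript_id,
        chrom=cassette.chrom,
        strand=cassette.strand,
        inclusion_up=(intron.start, cassette.start),
        inclusion_down=(cassette.end, intron.end),
        exclusion=(intron.start, intron.end),
    )


# ---------------------------------------------------------------------------
# The ERBB2-like worked example
# ---------------------------------------------------------------------------

@dataclass
class Erbb2LikeFixture:
    reference: SimulatedReference
    index: ReferenceIndex
    genome: dict[str, str]
    parent: TranscriptModel
    isoform: TranscriptModel
    truth: EventTruth
    event: EventDef
    cassette_peptide: str  # 34 residues encoded by the cassette
    core_peptide: str  # the 19-mer from the printed immunogen
    downstream_intron_seq: str  # sense sequence after the cassette 3' end
    ugg_window: tuple[int, int]  # 1-based downstream offsets


def _ugg_downstream_segment(total_len: int = 100) -> str:
    """Intronic segment downstream of the cassette with the UGG-rich window
    planted at 1-based offsets 47-60 and TGG-free flanks."""
    window = "GGTGGTGGTGGTGG"  # TGG at offsets 49, 52, 55, 58
    head = "GT" + "AC" * 22  # offsets 1..46, no T after position 2
    tail_len = total_len - len(head) - len(window) - 2
    tail = ("CA" * ((tail_len + 1) // 2))[:tail_len]
    seg = head + window + tail + "AG"
    assert len(seg) == total_len and seg.index(window) == 46
    return seg


def make_erbb2_like_fixture(seed: int = 20) -> Erbb2LikeFixture:
    """A 27-exon coding gene plus an isoform carrying a 102-nt in-frame
    cassette exon inside intron 14, whose translation contains the 19-mer
    core of the printed immunogen peptide; a UGG-rich window sits at 47-60 bp
    downstream of the cassette's 3' end.

    The 15 residues flanking the 19-mer are synthetic placeholders (the
    complete cassette peptide is not printed in full); only the 19-mer is
    sequence-faithful.
    """
    n_exons = 27
    host_intron = 14
    rng = np.random.default_rng(seed)
    exon_lengths = [120] * n_exons
    intron_lengths = [200] * (n_exons - 1)
    offset = 58
    downstream = _ugg_downstream_segment(100)
    intron_lengths[host_intron - 1] = offset + 102 + len(downstream)
    block, layout = _build_gene(
        rng, "ERBB2L", "chrE", "+", 0, exon_lengths, intron_lengths, pad=200
    )
    reference = SimulatedReference(
        {"chrE": bytearray(block.encode())}, {"ERBB2L": layout}
    )
    synth_n, synth_c = "GASPGTSG", "APTSLQG"  # synthetic flanks, 8 + 7 aa
    cassette_peptide = synth_n + CASSETTE_CORE_PEPTIDE + synth_c
    assert len(cassette_peptide) == 34
    cassette_seq = "".join(CODON_OF[aa] for aa in cassette_peptide)
    assert len(cassette_seq) == 102
    model, truth = apply_event(
        reference,
        "ERBB2L",
        EventSpec(
            "cryptic_exon",
            {
                "host_intron": host_intron,
                "cassette_seq": cassette_seq,
                "offset": offset,
                "downstream_override": downstream,
            },
        ),
        seed=seed,
        transcript_id="ERBB2L.i14e",
    )
    truth.planted["cassette_peptide"] = cassette_peptide
    truth.planted["ugg_window"] = (47, 60)
    event = event_def_from_truth(truth, reference)
    cassette = truth.planted["cassette_genomic"]
    genome = reference.genome_str()
    down_seq = genome["chrE"][cassette.end : cassette.end + len(downstream)]
    return Erbb2LikeFixture(
        reference=reference,
        index=reference.index,
        genome=genome,
        parent=reference.reference_model("ERBB2L"),
        isoform=model,
        truth=truth,
        event=event,
        cassette_peptide=cassette_peptide,
        core_peptide=CASSETTE_CORE_PEPTIDE,
        downstream_intron_seq=down_seq,
        ugg_window=(47, 60),
    )


# ---------------------------------------------------------------------------
# Whole-dataset simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimConfig
    reference: SimulatedReference
    index: ReferenceIndex
    models: list[TranscriptModel]  # parents + novel isoforms, with support
    truths: list[EventTruth]
    cage_peaks: list[GenomicInterval]
    sj_tables: list[JunctionCountTable]
    event: Optional[EventDef]


def simulate_dataset(config: SimConfig = SimConfig()) -> SimulatedDataset:
    """One end-to-end synthetic study: reference + one planted event per gene
    (kinds cycling; gene 1 always carries the cryptic exon), read support, CAGE
    peaks, and per-sample junction tables for the first cryptic-exon event."""
    reference = make_reference(config)
    rng = np.random.default_rng(config.seed + 1)
    sample_ids = [f"S{s + 1:02d}" for s in range(config.samples)]

    truths: list[EventTruth] = []
    novel: list[TranscriptModel] = []
    gene_ids = sorted(reference.layouts)
    for i, gene_id in enumerate(gene_ids):
        preferred = "cryptic_exon" if i == 0 else EVENT_KINDS[i % len(EVENT_KINDS)]
        kinds = [preferred] + [k for k in EVENT_KINDS if k != preferred]
        for kind in kinds:
            params = {"plant_ugg": True} if kind == "cryptic_exon" else {}
            try:
                model, truth = apply_event(
                    reference, gene_id, EventSpec(kind, params),
                    seed=config.seed + 100 + i,
                )
            except InfeasibleEventError:
                continue
            novel.append(model)
            truths.append(truth)
            break

    models: list[TranscriptModel] = []
    for gene_id in gene_ids:
        parent = reference.reference_model(gene_id)
        support = {s: int(rng.poisson(20) + 3) for s in sample_ids}
        models.append(
            TranscriptModel(
                parent.transcript_id, parent.gene_id, parent.exons, support
            )
        )
    for j, m in enumerate(novel):
        if j % 7 == 6:  # a slice of barely-supported isoforms for the filter
            support = {s: 0 for s in sample_ids}
            support[sample_ids[0]] = int(rng.integers(0, 3))
        else:
            support = {s: int(rng.poisson(8) + 1) for s in sample_ids}
        models.append(TranscriptModel(m.transcript_id, m.gene_id, m.exons, support))

    cage = reference.cage_peaks(config.cage_halfwidth)
    event = None
    sj_tables: list[JunctionCountTable] = []
    cryptic = [t for t in truths if t.kind == "cryptic_exon"]
    if cryptic:
        event = event_def_from_truth(cryptic[0], reference)
        sj_tables = simulate_junction_counts(
            event, config, rng=np.random.default_rng(config.seed + 2)
        )
        # background counts on annotated junctions
        index = reference.index
        for table in sj_tables:
            for chrom, strand, a, b in sorted(index.junction_set):
                if (chrom, a, b) in table.records:
                    continue
                table.add(
                    SJRecord(
                        chrom=chrom, start=a, end=b, strand=strand, motif=1,
                        annotated=True,
                        unique_reads=int(rng.poisson(30)),
                        multi_reads=0, max_overhang=50,
                    )
                )
    return SimulatedDataset(
        config=config,
        reference=reference,
        index=reference.index,
        models=models,
        truths=truths,
        cage_peaks=cage,
        sj_tables=sj_tables,
        event=event,
    )


def write_dataset(dataset: SimulatedDataset, outdir: Union[str, Path]) -> dict[str, Path]:
    """Emit the dataset as files (FASTA/GTF/TSV/BED/SJ tables/truth table)."""
    from . import io as iomod

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fa",
        "reference": out / "reference.gtf",
        "isoforms": out / "isoforms.gtf",
        "support": out / "support.tsv",
        "cage": out / "cage.bed",
        "truth": out / "truth.tsv",
    }
    iomod.write_genome_fasta(dataset.reference.genome_str(), paths["genome"])
    iomod.write_annotation_gtf(dataset.index, paths["reference"])
    iomod.write_transcripts_gtf(dataset.models, paths["isoforms"])
    sample_ids = sorted({s for m in dataset.models for s in (m.support or {})})
    with open(paths["support"], "w") as fh:
        fh.write("transcript_id\t" + "\t".join(sample_ids) + "\n")
        for m in sorted(dataset.models, key=lambda x: x.transcript_id):
            row = [str((m.support or {}).get(s, 0)) for s in sample_ids]
            fh.write(m.transcript_id + "\t" + "\t".join(row) + "\n")
    iomod.write_cage_bed(dataset.cage_peaks, paths["cage"])
    truth_rows = [
        {
            "transcript_id": t.transcript_id,
            "gene_id": t.gene_id,
            "kind": t.kind,
            "expected_category": t.expected_category,
            "expected_orf_class": t.expected_orf_class or "",
        }
        for t in dataset.truths
    ]
    iomod.write_report(truth_rows, paths["truth"])
    sj_dir = out / "SJ"
    sj_dir.mkdir(exist_ok=True)
    for table in dataset.sj_tables:
        p = sj_dir / f"{table.sample_id}.SJ.out.tab"
        iomod.write_sj_table(table, p)
        paths[f"sj_{table.sample_id}"] = p
    return paths
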