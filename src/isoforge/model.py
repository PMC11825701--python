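"""Core domain types: genomic intervals, transcript models, and the reference index.

Coordinate convention
---------------------
All in-memory coordinates are 0-based, half-open ``[start, end)`` on the
forward genomic strand. File dialects (GTF: 1-based inclusive; STAR
``SJ.out.tab``: 1-based inclusive first/last intronic base) are converted at
the I/O boundary (:mod:`isoforge.io`), never inside analysis code.

A *junction* is the intron it spans, written ``(donor_side, acceptor_side)``
in genomic orientation: ``(upstream_exon.end, downstream_exon.start)``. On the
minus strand the biological donor is the right-hand coordinate; helpers below
resolve strand-aware donor/acceptor sites.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

STRANDS = ("+", "-")


class IsoforgeError(Exception):
    """Base class for all package errors."""


class ValidationError(IsoforgeError):
    """A domain-type invariant was violated."""


class ConfigError(IsoforgeError):
    """An invalid configuration value."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded, 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def strictly_contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.start
            and other.end < self.end
        )


Junction = tuple[int, int]


@dataclass(frozen=True)
class SpliceChain:
    """Ordered donor/acceptor junction pairs of a multi-exon transcript.

    Junctions are stored in genomic order as ``(intron_start, intron_end)``
    0-based half-open pairs; empty for mono-exon transcripts.
    """

    junctions: tuple[Junction, ...]

    @classmethod
    def from_model(cls, model: "TranscriptModel") -> "SpliceChain":
        return cls(model.junctions)

    def __len__(self) -> int:
        return len(self.junctions)


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript's strand-aware exon chain plus per-sample read support."""

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    support: Optional[Mapping[str, int]] = None

    def __post_init__(self) -> None:
        if len(self.exons) < 1:
            raise ValidationError(
                f"transcript {self.transcript_id}: needs at least one exon"
            )
        object.__setattr__(self, "exons", tuple(self.exons))
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValidationError(
                f"transcript {self.transcript_id}: exons span multiple "
                "chromosomes or strands"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.start:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exons not sorted by start"
                )
            if b.start < a.end + 1:
                raise ValidationError(
                    f"transcript {self.transcript_id}: overlapping or adjacent "
                    f"exons at {a.chrom}:{a.start}-{a.end} / {b.start}-{b.end}"
                )
        if self.support is not None:
            for sample, count in self.support.items():
                if count < 0:
                    raise ValidationError(
                        f"transcript {self.transcript_id}: negative support "
                        f"for sample {sample}"
                    )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def length(self) -> int:
        """Spliced (mature transcript) length in nt."""
        return sum(e.length for e in self.exons)

    @property
    def junctions(self) -> tuple[Junction, ...]:
        return tuple(
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        )

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        return tuple(
            GenomicInterval(self.chrom, a, b, self.strand)
            for a, b in self.junctions
        )

    @property
    def tss(self) -> int:
        """Genomic coordinate (0-based) of the first transcribed base."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """Genomic coordinate (0-based) of the last transcribed base."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def total_support(self) -> int:
        if self.support is None:
            return 0
        return int(sum(self.support.values()))

    def exon_lengths_transcript_order(self) -> list[int]:
        lengths = [e.length for e in self.exons]
        return lengths if self.strand == "+" else lengths[::-1]

    def transcript_to_genomic(self, t_start: int, t_end: int) -> list[GenomicInterval]:
        """Map a transcript-space interval onto genomic exon segments.

        Transcript coordinates are 0-based half-open, measured 5'->3' along
        the mature transcript (strand-aware).
        """
        if not (0 <= t_start < t_end <= self.length):
            raise ValidationError(
                f"transcript {self.transcript_id}: transcript-space interval "
                f"[{t_start},{t_end}) outside [0,{self.length})"
            )
        exons = self.exons if self.strand == "+" else self.exons[::-1]
        segments: list[GenomicInterval] = []
        offset = 0
        for exon in exons:
            lo = max(t_start, offset)
            hi = min(t_end, offset + exon.length)
            if lo < hi:
                if self.strand == "+":
                    g0 = exon.start + (lo - offset)
                    g1 = exon.start + (hi - offset)
                else:
                    g1 = exon.end - (lo - offset)
                    g0 = exon.end - (hi - offset)
                segments.append(GenomicInterval(self.chrom, g0, g1, self.strand))
            offset += exon.length
        segments.sort(key=lambda s: s.start)
        return segments

    def spliced_sequence(self, genome: Mapping[str, str]) -> str:
        """Mature transcript sequence in 5'->3' transcript orientation."""
        chrom_seq = genome[self.chrom]
        parts = [str(chrom_seq[e.start : e.end]) for e in self.exons]
        seq = "".join(parts).upper()
        if self.strand == "-":
            seq = reverse_complement(seq)
        return seq


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def donor_acceptor(junction: Junction, strand: str) -> tuple[int, int]:
    """Strand-aware (donor, acceptor) splice-site coordinates of a junction."""
    a, b = junction
    return (a, b) if strand == "+" else (b, a)


class ReferenceIndex:
    """Derived catalog of reference junctions, splice sites, ends, and exons.

    The oracle for novelty: every structural and end-validation decision is a
    set/interval lookup against this index.
    """

    def __init__(self, genes: Mapping[str, Sequence[TranscriptModel]]):
        self.genes: dict[str, list[TranscriptModel]] = {
            g: list(ts) for g, ts in genes.items()
        }
        self.transcripts: dict[str, TranscriptModel] = {}
        for gene_id, models in self.genes.items():
            for m in models:
                if m.transcript_id in self.transcripts:
                    raise ValidationError(
                        f"duplicate transcript_id {m.transcript_id!r} in reference"
                    )
                self.transcripts[m.transcript_id] = m

        self.junction_set: set[tuple[str, str, int, int]] = set()
        self.donor_set: set[tuple[str, str, int]] = set()
        self.acceptor_set: set[tuple[str, str, int]] = set()
        # full splice chain -> transcript ids sharing it
        self.chains: dict[tuple[str, str, tuple[Junction, ...]], list[str]] = {}
        # per (chrom, strand): list of (junctions, transcript_id) for sub-chain search
        self.chain_lists: dict[tuple[str, str], list[tuple[tuple[Junction, ...], str]]] = {}
        self.mono_exon: dict[tuple[str, str], list[TranscriptModel]] = {}
        self._tss: dict[tuple[str, str], list[int]] = {}
        self._tes: dict[tuple[str, str], list[int]] = {}
        # per (chrom, strand): interval tree of reference exons, data=gene_id
        self.exon_trees: dict[tuple[str, str], IntervalTree] = {}
        self.gene_spans: dict[str, GenomicInterval] = {}
        self.exon_union: dict[str, list[GenomicInterval]] = {}

        for gene_id, models in self.genes.items():
            g_start, g_end = None, None
            exon_ivs: list[GenomicInterval] = []
            for m in models:
                key = (m.chrom, m.strand)
                juncs = m.junctions
                if juncs:
                    self.chains.setdefault(
                        (m.chrom, m.strand, juncs), []
                    ).append(m.transcript_id)
                    self.chain_lists.setdefault(key, []).append(
                        (juncs, m.transcript_id)
                    )
                    for j in juncs:
                        self.junction_set.add((m.chrom, m.strand, j[0], j[1]))
                        d, a = donor_acceptor(j, m.strand)
                        self.donor_set.add((m.chrom, m.strand, d))
                        self.acceptor_set.add((m.chrom, m.strand, a))
                else:
                    self.mono_exon.setdefault(key, []).append(m)
                self._tss.setdefault(key, []).append(m.tss)
                self._tes.setdefault(key, []).append(m.tes)
                tree = self.exon_trees.setdefault(key, IntervalTree())
                for e in m.exons:
                    tree.addi(e.start, e.end, gene_id)
                    exon_ivs.append(e)
                g_start = m.start if g_start is None else min(g_start, m.start)
                g_end = m.end if g_end is None else max(g_end, m.end)
            if models:
                self.gene_spans[gene_id] = GenomicInterval(
                    models[0].chrom, g_start, g_end, models[0].strand
                )
                self.exon_union[gene_id] = _merge_intervals(exon_ivs)
        for key in self._tss:
            self._tss[key] = sorted(set(self._tss[key]))
        for key in self._tes:
            self._tes[key] = sorted(set(self._tes[key]))

    @property
    def tss_set(self) -> set[tuple[str, str, int]]:
        return {(c, s, p) for (c, s), ps in self._tss.items() for p in ps}

    @property
    def tes_set(self) -> set[tuple[str, str, int]]:
        return {(c, s, p) for (c, s), ps in self._tes.items() for p in ps}

    def has_junction(self, chrom: str, strand: str, junction: Junction) -> bool:
        return (chrom, strand, junction[0], junction[1]) in self.junction_set

    def nearest_tss_distance(self, model: TranscriptModel) -> Optional[int]:
        """Signed distance to nearest annotated same-strand TSS.

        Positive means the query 5' end lies downstream (in transcript
        orientation) of the nearest reference TSS.
        """
        return self._nearest_signed(self._tss, model.chrom, model.strand, model.tss)

    def nearest_tes_distance(self, model: TranscriptModel) -> Optional[int]:
        return self._nearest_signed(self._tes, model.chrom, model.strand, model.tes)

    def _nearest_signed(
        self,
        table: Mapping[tuple[str, str], list[int]],
        chrom: str,
        strand: str,
        pos: int,
    ) -> Optional[int]:
        positions = table.get((chrom, strand))
        if not positions:
            return None
        i = bisect.bisect_left(positions, pos)
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(positions):
                d = pos - positions[j]
                if best is None or abs(d) < abs(best):
                    best = d
        return best if strand == "+" else -best

    def overlapping_genes(
        self, model: TranscriptModel, strand: Optional[str] = None
    ) -> dict[str, int]:
        """gene_id -> total exonic overlap (nt) with the query's exons."""
        strand = strand or model.strand
        tree = self.exon_trees.get((model.chrom, strand))
        if tree is None:
            return {}
        overlap: dict[str, int] = {}
        for exon in model.exons:
            for hit in tree.overlap(exon.start, exon.end):
                ov = min(exon.end, hit.end) - max(exon.start, hit.begin)
                overlap[hit.data] = overlap.get(hit.data, 0) + ov
        return overlap

    def gene_introns(self, gene_id: str) -> list[tuple[str, int, GenomicInterval]]:
        """All introns of a gene as (transcript_id, transcript-orientation
        1-based intron index, interval)."""
        out = []
        for m in self.genes.get(gene_id, []):
            introns = m.introns
            n = len(introns)
            for gi, intron in enumerate(introns):
                idx = gi + 1 if m.strand == "+" else n - gi
                out.append((m.transcript_id, idx, intron))
        return out


def _merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    ivs = sorted(intervals, key=lambda x: (x.start, x.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(
                    iv.chrom, merged[-1].start, iv.end, iv.strand
                )
        else:
            merged.append(iv)
    return merged


@dataclass
class SJRecord:
    """One splice junction row from a STAR ``SJ.out.tab`` table (internal coords)."""

    chrom: str
    start: int  # 0-based first intronic base
    end: int  # 0-based half-open (one past last intronic base)
    strand: Optional[str]  # None = undetermined (STAR code 0)
    motif: int = 0
    annotated: bool = False
    unique_reads: int = 0
    multi_reads: int = 0
    max_overhang: int = 0


@dataclass
class JunctionCountTable:
    """Per-sample splice-junction read counts keyed by intron coordinates."""

    sample_id: str
    records: dict[tuple[str, int, int], SJRecord] = field(default_factory=dict)

    def add(self, rec: SJRecord) -> None:
        key = (rec.chrom, rec.start, rec.end)
        if key in self.records:
            existing = self.records[key]
            existing.unique_reads += rec.unique_reads
            existing.multi_reads += rec.multi_reads
            existing.max_overhang = max(existing.max_overhang, rec.max_overhang)
        else:
            self.records[key] = rec

    def unique_count(
        self, chrom: str, junction: Junction, strand: Optional[str] = None
    ) -> int:
        """Unique-read count for a junction; 0 when absent.

        Rows with undetermined strand match regardless of the requested
        strand; stranded rows must agree when a strand is requested.
        """
        rec = self.records.get((chrom, junction[0], junction[1]))
        if rec is None:
            return 0
        if strand is not None and rec.strand is not None and rec.strand != strand:
            return 0
        return rec.unique_reads

    def total_unique(self) -> int:
        return sum(r.unique_reads for r in self.records.values())
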