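"""SQANTI-style structural classification of transcript models.

Multi-exon categories are decided purely from the splice chain against the
reference index:

* ``FSM``  — the query's full junction chain equals a same-strand reference
  chain (transcript ends are free to vary).
* ``ISM``  — the chain is a *contiguous* sub-chain of one reference chain
  (5'- or 3'-truncated isoform).
* ``NIC``  — neither, but every donor and acceptor is an annotated splice
  site (a novel combination of known sites).
* ``NNC``  — at least one splice site is absent from the reference.

Mono-exon transcripts: ``FSM`` when contained in a same-strand reference
mono-exon transcript, else ``genic`` / ``antisense`` / ``intergenic`` by
overlap. Queries spanning two non-overlapping genes are set aside as
``fusion_like`` and excluded from downstream event analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .model import (
    ConfigError,
    GenomicInterval,
    IsoforgeError,
    Junction,
    ReferenceIndex,
    TranscriptModel,
    donor_acceptor,
)

CATEGORIES = (
    "FSM",
    "ISM",
    "NIC",
    "NNC",
    "genic",
    "antisense",
    "intergenic",
    "fusion_like",
)

#: Categories counted as "known" when re-annotating.
DEFAULT_KNOWN_CATEGORIES = frozenset({"FSM"})


class MissingSupportError(IsoforgeError):
    """A transcript reached the support filter without read-support counts."""


@dataclass(frozen=True)
class CrypticExonCall:
    """An internal exon lying wholly inside a reference intron."""

    exon: GenomicInterval
    host_transcript_id: str
    host_intron_index: int  # 1-based, transcript orientation
    mode: str  # strict | relaxed


@dataclass
class StructuralCall:
    transcript_id: str
    category: str
    novelty: Optional[str] = None  # known | novel (set by reannotate)
    assigned_gene: Optional[str] = None
    matched_reference_transcript: Optional[str] = None
    novel_junctions: list[Junction] = field(default_factory=list)
    novel_splice_sites: list[int] = field(default_factory=list)
    cryptic_exons: list[CrypticExonCall] = field(default_factory=list)


@dataclass(frozen=True)
class FilterConfig:
    min_support: int = 3

    def __post_init__(self) -> None:
        if self.min_support < 1:
            raise ConfigError("min_support must be >= 1")


def _assign_gene(model: TranscriptModel, index: ReferenceIndex):
    """Same-strand gene with maximal exonic overlap; detect fusion-like span."""
    overlaps = index.overlapping_genes(model)
    if not overlaps:
        return None, False
    best = max(overlaps, key=lambda g: (overlaps[g], g))
    fusion = False
    if len(overlaps) > 1:
        spans = [index.gene_spans[g] for g in overlaps]
        for i, a in enumerate(spans):
            for b in spans[i + 1 :]:
                if not a.overlaps(b):
                    fusion = True
    return best, fusion


def _is_contiguous_subchain(
    query: tuple[Junction, ...], reference: tuple[Junction, ...]
) -> bool:
    n, m = len(query), len(reference)
    if n == 0 or n > m:
        return False
    return any(reference[i : i + n] == query for i in range(m - n + 1))


def _match_fsm(model: TranscriptModel, candidates: Sequence[str], index: ReferenceIndex) -> str:
    """Tie-break FSM matches: minimal total end distance, then lexicographic id."""

    def key(tid: str):
        ref = index.transcripts[tid]
        return (abs(model.start - ref.start) + abs(model.end - ref.end), tid)

    return min(candidates, key=key)


def classify_transcript(model: TranscriptModel, index: ReferenceIndex) -> StructuralCall:
    """Assign exactly one structural category to a transcript model."""
    gene, fusion = _assign_gene(model, index)
    call = StructuralCall(
        transcript_id=model.transcript_id, category="", assigned_gene=gene
    )
    if fusion:
        call.category = "fusion_like"
        return call
    chain = model.junctions
    chrom, strand = model.chrom, model.strand

    if gene is None:
        opposite = index.overlapping_genes(
            model, strand="-" if strand == "+" else "+"
        )
        call.category = "antisense" if opposite else "intergenic"
        return call

    if len(chain) == 0:
        for ref in index.mono_exon.get((chrom, strand), []):
            if ref.start <= model.start and model.end <= ref.end:
                call.category = "FSM"
                call.matched_reference_transcript = ref.transcript_id
                return call
        call.category = "genic"
        return call

    exact = index.chains.get((chrom, strand, chain))
    if exact:
        call.category = "FSM"
        call.matched_reference_transcript = _match_fsm(model, exact, index)
        return call

    ism_hits = [
        tid
        for ref_chain, tid in index.chain_lists.get((chrom, strand), [])
        if _is_contiguous_subchain(chain, ref_chain)
    ]
    if ism_hits:
        call.category = "ISM"
        call.matched_reference_transcript = _match_fsm(model, ism_hits, index)
        return call

    novel_sites = []
    for j in chain:
        d, a = donor_acceptor(j, strand)
        if (chrom, strand, d) not in index.donor_set:
            novel_sites.append(d)
        if (chrom, strand, a) not in index.acceptor_set:
            novel_sites.append(a)
    call.novel_junctions = [j for j in chain if not index.has_junction(chrom, strand, j)]
    call.novel_splice_sites = sorted(set(novel_sites))
    call.category = "NNC" if novel_sites else "NIC"
    return call


def detect_intron_derived_exons(
    model: TranscriptModel,
    call: StructuralCall,
    index: ReferenceIndex,
    mode: str = "strict",
) -> list[CrypticExonCall]:
    """Report internal exons lying strictly inside a reference intron.

    ``strict`` additionally requires the flanking query junctions to reuse
    the host intron's own donor and acceptor — the cassette pattern of an
    intron-derived exon spliced into an otherwise unchanged intron. In
    ``relaxed`` mode only strict containment (and absence of reference-exon
    overlap) is required.
    """
    if mode not in ("strict", "relaxed"):
        raise ConfigError(f"unknown cryptic-exon mode {mode!r}")
    if call.assigned_gene is None or model.n_exons < 3:
        return []
    gene = call.assigned_gene
    exon_union = index.exon_union.get(gene, [])
    calls: list[CrypticExonCall] = []
    for i in range(1, model.n_exons - 1):
        exon = model.exons[i]
        if any(exon.overlaps(ref_exon) for ref_exon in exon_union):
            continue
        prev_junction = model.junctions[i - 1]  # (prev.end, exon.start)
        next_junction = model.junctions[i]  # (exon.end, next.start)
        for host_tid, intron_index, intron in index.gene_introns(gene):
            if not intron.strictly_contains(exon):
                continue
            if mode == "strict":
                if prev_junction[0] != intron.start or next_junction[1] != intron.end:
                    continue
            calls.append(
                CrypticExonCall(
                    exon=exon,
                    host_transcript_id=host_tid,
                    host_intron_index=intron_index,
                    mode=mode,
                )
            )
    calls.sort(key=lambda c: (c.exon.start, c.host_transcript_id))
    return calls


def classify(
    models: Sequence[TranscriptModel],
    index: ReferenceIndex,
    cryptic_mode: str = "strict",
) -> list[StructuralCall]:
    """Classify a batch and attach cryptic-exon calls."""
    calls = []
    for model in models:
        call = classify_transcript(model, index)
        if call.category not in ("fusion_like",):
            call.cryptic_exons = detect_intron_derived_exons(
                model, call, index, mode=cryptic_mode
            )
        calls.append(call)
    return calls


def filter_models(
    models: Sequence[TranscriptModel], cfg: FilterConfig = FilterConfig()
) -> tuple[list[TranscriptModel], list[dict]]:
    """Drop transcripts whose total read support across samples is below the
    threshold (default: fewer than 3 supporting reads)."""
    retained: list[TranscriptModel] = []
    drop_log: list[dict] = []
    for m in models:
        if m.support is None:
            raise MissingSupportError(
                f"transcript {m.transcript_id} has no read-support counts"
            )
        total = m.total_support
        if total >= cfg.min_support:
            retained.append(m)
        else:
            drop_log.append(
                {
                    "transcript_id": m.transcript_id,
                    "total_support": total,
                    "reason": f"support {total} < {cfg.min_support}",
                }
            )
    return retained, drop_log


def reannotate(
    calls: Sequence[StructuralCall],
    known_categories=DEFAULT_KNOWN_CATEGORIES,
) -> pd.DataFrame:
    """Label calls known/novel in place and return the per-subtype tally."""
    known = frozenset(known_categories)
    for call in calls:
        call.novelty = "known" if call.category in known else "novel"
    counts = {cat: 0 for cat in CATEGORIES}
    for call in calls:
        counts[call.category] += 1
    tally = pd.DataFrame(
        {
            "category": list(CATEGORIES),
            "count": [counts[c] for c in CATEGORIES],
            "novelty": [
                "known" if c in known else "novel" for c in CATEGORIES
            ],
        }
    )
    return tally
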