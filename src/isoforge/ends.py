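"""Transcript 5'/3' end validation against CAGE peaks and polyA motifs.

A 5' end is CAGE-supported when it lies within ``window`` nt (inclusive,
default 50) of a same-strand CAGE peak interval (distance 0 inside the
peak). A 3' end is polyA-supported when one of the configured hexamer
motifs (default AATAAA, ATTAAA) occurs in the final ``search_span`` nt of
the mature transcript sequence. Signed distances to the nearest annotated
TSS/TES are reported for distribution summaries; the closest reference end
is always the one measured.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    ConfigError,
    GenomicInterval,
    ReferenceIndex,
    TranscriptModel,
)


@dataclass(frozen=True)
class EndConfig:
    window: int = 50
    polya_motifs: tuple[str, ...] = ("AATAAA", "ATTAAA")
    search_span: int = 50

    def __post_init__(self) -> None:
        if self.window <= 0 or self.search_span <= 0:
            raise ConfigError("window and search_span must be positive")
        for m in self.polya_motifs:
            if not m or set(m) - set("ACGT"):
                raise ConfigError(f"polyA motif {m!r} is not uppercase DNA")


@dataclass
class EndSupport:
    transcript_id: str
    tss_distance: Optional[int] = None  # signed nt to nearest annotated TSS
    cage_distance: Optional[int] = None  # nt to nearest CAGE peak interval
    cage_within_window: bool = False
    tes_distance: Optional[int] = None
    polya_motif_found: bool = False
    polya_motif: Optional[str] = None
    polya_offset: Optional[int] = None  # nt from motif end to transcript 3' end


def _peak_distance(pos: int, peaks: Sequence[GenomicInterval]) -> Optional[int]:
    best = None
    for p in peaks:
        if p.start <= pos < p.end:
            return 0
        d = min(abs(pos - p.start), abs(pos - (p.end - 1)))
        if best is None or d < best:
            best = d
    return best


def tss_support(
    model: TranscriptModel,
    cage_peaks: Sequence[GenomicInterval],
    index: Optional[ReferenceIndex],
    cfg: EndConfig = EndConfig(),
    support: Optional[EndSupport] = None,
) -> EndSupport:
    """Fill the 5'-end fields: CAGE peak distance/flag and TSS distance."""
    out = support or EndSupport(transcript_id=model.transcript_id)
    pos = model.tss
    relevant = [
        p for p in cage_peaks if p.chrom == model.chrom and p.strand == model.strand
    ]
    d = _peak_distance(pos, relevant)
    out.cage_distance = d
    out.cage_within_window = d is not None and d <= cfg.window
    if index is not None:
        out.tss_distance = index.nearest_tss_distance(model)
    return out


def polya_support(
    model: TranscriptModel,
    genome: Mapping[str, str],
    cfg: EndConfig = EndConfig(),
    index: Optional[ReferenceIndex] = None,
    support: Optional[EndSupport] = None,
) -> EndSupport:
    """Fill the 3'-end fields: motif scan of the terminal transcript sequence.

    When several motif hits exist the 3'-most is reported; transcripts
    shorter than the search span are scanned in full.
    """
    out = support or EndSupport(transcript_id=model.transcript_id)
    seq = model.spliced_sequence(genome)
    span = min(cfg.search_span, len(seq))
    tail = seq[len(seq) - span :]
    best = None  # (offset from 3' end of motif end, motif)
    for motif in cfg.polya_motifs:
        idx = tail.rfind(motif)
        if idx != -1:
            offset = span - (idx + len(motif))
            if best is None or offset < best[0]:
                best = (offset, motif)
    if best is not None:
        out.polya_motif_found = True
        out.polya_offset, out.polya_motif = best
    if index is not None:
        out.tes_distance = index.nearest_tes_distance(model)
    return out


def end_support(
    model: TranscriptModel,
    cage_peaks: Sequence[GenomicInterval],
    genome: Mapping[str, str],
    index: Optional[ReferenceIndex],
    cfg: EndConfig = EndConfig(),
) -> EndSupport:
    out = tss_support(model, cage_peaks, index, cfg)
    return polya_support(model, genome, cfg, index, support=out)


def end_summary(
    supports: Sequence[EndSupport],
    calls,
    bins: Optional[np.ndarray] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-structural-category support rates plus a TSS-distance histogram.

    ``calls`` is any sequence with ``transcript_id`` and ``category``
    attributes (structural calls). Returns ``(rates, histogram)``.
    """
    cat_of = {c.transcript_id: c.category for c in calls}
    rows = []
    for s in supports:
        rows.append(
            {
                "category": cat_of.get(s.transcript_id, "unclassified"),
                "cage": s.cage_within_window,
                "polya": s.polya_motif_found,
                "tss_distance": s.tss_distance,
            }
        )
    frame = pd.DataFrame(rows)
    if frame.empty:
        return pd.DataFrame(), pd.DataFrame()
    rates = (
        frame.groupby("category", sort=True)
        .agg(n=("cage", "size"), cage_rate=("cage", "mean"), polya_rate=("polya", "mean"))
        .reset_index()
    )
    if bins is None:
        bins = np.arange(-500, 501, 50)
    dists = frame["tss_distance"].dropna().to_numpy()
    counts, edges = np.histogram(dists, bins=bins)
    hist = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
    return rates, hist
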