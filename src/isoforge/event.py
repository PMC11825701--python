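"""Cryptic-exon inclusion events: cohort quantification and motif context.

An inclusion event is three junctions: two *inclusion* junctions (host
intron donor -> cassette acceptor; cassette donor -> host intron acceptor)
and one *exclusion* junction (the unbroken host intron). The per-sample
supporting-read ratio is

    psi_hat = mean(inc_up, inc_down) / (mean(inc_up, inc_down) + exc)

computed from unique junction reads of a STAR ``SJ.out.tab`` table; a
sum-based alternative is available via ``ratio_mode="sum"``. A scanner for
ESRP-type UGG-rich intronic windows downstream of the cassette's 3' end
supports the splicing-regulator analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    ConfigError,
    IsoforgeError,
    Junction,
    JunctionCountTable,
    ReferenceIndex,
)
from .structural import CrypticExonCall


@dataclass(frozen=True)
class EventDef:
    name: str
    chrom: str
    strand: str
    inclusion_up: Junction  # host donor -> cassette acceptor (genomic order)
    inclusion_down: Junction  # cassette donor -> host acceptor (genomic order)
    exclusion: Junction  # full host intron

    def __post_init__(self) -> None:
        exc_a, exc_b = self.exclusion
        if not (
            exc_a == self.inclusion_up[0]
            and exc_b == self.inclusion_down[1]
            and self.inclusion_up[1] < self.inclusion_down[0]
        ):
            raise ConfigError(
                f"event {self.name}: exclusion junction must span both "
                "inclusion junctions"
            )


@dataclass(frozen=True)
class PresenceRule:
    min_reads_each_inclusion: int = 2

    def __post_init__(self) -> None:
        if self.min_reads_each_inclusion < 1:
            raise ConfigError("min_reads_each_inclusion must be >= 1")


@dataclass
class EventQuant:
    sample_id: str
    inc_up: int
    inc_down: int
    exc: int
    ratio: Optional[float]  # None when all counts are zero
    present: bool


@dataclass(frozen=True)
class MotifConfig:
    motif: str = "TGG"  # UGG on the RNA strand
    window_len: int = 14
    min_motif_fraction: float = 0.5
    search_range: Optional[int] = None  # nt downstream of the exon 3' end

    def __post_init__(self) -> None:
        if self.window_len < 3:
            raise ConfigError("window_len must be >= 3")
        if set(self.motif) - set("ACGT"):
            raise ConfigError("motif must be uppercase DNA")


@dataclass(frozen=True)
class MotifWindow:
    start_offset: int  # 1-based offset downstream of the exon 3' end
    end_offset: int  # inclusive
    motif_count: int
    motif_fraction: float


def event_from_cryptic_call(
    call: CrypticExonCall, index: ReferenceIndex, name: Optional[str] = None
) -> EventDef:
    """Derive the three event junctions from a strict-mode cryptic-exon call."""
    if call.mode != "strict":
        raise ConfigError(
            "event definitions require a strict-mode cryptic-exon call "
            "(flanking junctions must reuse the host intron boundaries)"
        )
    host = index.transcripts[call.host_transcript_id]
    introns = host.introns
    gi = (
        call.host_intron_index - 1
        if host.strand == "+"
        else len(introns) - call.host_intron_index
    )
    intron = introns[gi]
    exon = call.exon
    return EventDef(
        name=name or f"{call.host_transcript_id}_i{call.host_intron_index}e",
        chrom=exon.chrom,
        strand=exon.strand,
        inclusion_up=(intron.start, exon.start),
        inclusion_down=(exon.end, intron.end),
        exclusion=(intron.start, intron.end),
    )


def quantify_event(
    event: EventDef,
    table: JunctionCountTable,
    rule: PresenceRule = PresenceRule(),
    ratio_mode: str = "mean",
) -> EventQuant:
    """Per-sample inclusion/exclusion read counts and supporting-read ratio.

    Junctions absent from the table count as zero. Rows with undetermined
    strand match by coordinates alone.
    """
    if ratio_mode not in ("mean", "sum"):
        raise ConfigError(f"unknown ratio_mode {ratio_mode!r}")
    inc_up = table.unique_count(event.chrom, event.inclusion_up, event.strand)
    inc_down = table.unique_count(event.chrom, event.inclusion_down, event.strand)
    exc = table.unique_count(event.chrom, event.exclusion, event.strand)
    inclusion = (
        (inc_up + inc_down) / 2.0 if ratio_mode == "mean" else float(inc_up + inc_down)
    )
    denom = inclusion + exc
    ratio = inclusion / denom if denom > 0 else None
    present = (
        inc_up >= rule.min_reads_each_inclusion
        and inc_down >= rule.min_reads_each_inclusion
    )
    return EventQuant(
        sample_id=table.sample_id,
        inc_up=inc_up,
        inc_down=inc_down,
        exc=exc,
        ratio=ratio,
        present=present,
    )


def cohort_prevalence(
    event: EventDef,
    tables: Sequence[JunctionCountTable],
    rule: PresenceRule = PresenceRule(),
) -> tuple[float, list[EventQuant]]:
    """Fraction of cohort samples in which the event is called present."""
    if not tables:
        raise ConfigError("cohort_prevalence requires at least one sample table")
    seen: set[str] = set()
    quants: list[EventQuant] = []
    for table in tables:
        if table.sample_id in seen:
            raise IsoforgeError(f"duplicate sample_id {table.sample_id!r}")
        seen.add(table.sample_id)
        quants.append(quantify_event(event, table, rule))
    prevalence = sum(q.present for q in quants) / len(quants)
    return prevalence, quants


@dataclass
class RelativeSupportResult:
    per_sample: pd.DataFrame  # sample_id, group, ratio, relative_ratio
    group_means: pd.Series
    t_statistic: Optional[float]
    p_value: Optional[float]


def relative_support_ratio(
    quants: Sequence[EventQuant],
    group_labels: Mapping[str, str],
    baseline_group: str,
) -> RelativeSupportResult:
    """Supporting-read ratios normalized to the baseline group's mean.

    The baseline group's mean relative ratio is 1 by construction. When
    exactly two groups are present a two-sided Welch t statistic comparing
    their relative ratios is reported.
    """
    rows = []
    for q in quants:
        if q.sample_id not in group_labels:
            raise ConfigError(f"sample {q.sample_id!r} has no group label")
        rows.append(
            {
                "sample_id": q.sample_id,
                "group": group_labels[q.sample_id],
                "ratio": q.ratio,
            }
        )
    frame = pd.DataFrame(rows)
    base = frame.loc[frame["group"] == baseline_group, "ratio"].dropna()
    if base.empty:
        raise ConfigError(f"baseline group {baseline_group!r} is empty")
    base_mean = float(base.mean())
    if base_mean <= 0:
        raise ConfigError("baseline group mean ratio must be > 0")
    frame["relative_ratio"] = frame["ratio"] / base_mean
    group_means = frame.groupby("group")["relative_ratio"].mean()
    groups = sorted(frame["group"].dropna().unique())
    t_stat = p_val = None
    if len(groups) == 2:
        a = frame.loc[frame["group"] == groups[0], "relative_ratio"].dropna()
        b = frame.loc[frame["group"] == groups[1], "relative_ratio"].dropna()
        if len(a) > 1 and len(b) > 1:
            if np.allclose(a.var(ddof=1) + b.var(ddof=1), 0) and math.isclose(
                a.mean(), b.mean()
            ):
                t_stat, p_val = 0.0, 1.0
            else:
                res = stats.ttest_ind(a, b, equal_var=False)
                t_stat, p_val = float(res.statistic), float(res.pvalue)
    return RelativeSupportResult(
        per_sample=frame,
        group_means=group_means,
        t_statistic=t_stat,
        p_value=p_val,
    )


def count_motifs(seq: str, motif: str) -> int:
    """Occurrences of ``motif`` in ``seq``, overlapping occurrences allowed."""
    count = start = 0
    while True:
        idx = seq.find(motif, start)
        if idx == -1:
            return count
        count += 1
        start = idx + 1


def scan_ugg_rich(
    intron_seq: str, cfg: MotifConfig = MotifConfig()
) -> list[MotifWindow]:
    """Rank motif-rich windows downstream of a cassette exon's 3' end.

    ``intron_seq`` is the sense-strand sequence starting at the first
    intronic base after the exon (1-based offset 1). Windows of
    ``window_len`` nt are scored by motif occurrence count; windows whose
    motif fraction (motif-length x count / window length) reaches
    ``min_motif_fraction`` are returned, ranked by score then 5'-most.
    """
    seq = intron_seq.upper()
    if cfg.search_range is not None:
        seq = seq[: cfg.search_range]
    w = cfg.window_len
    if len(seq) < w:
        return []
    hits = []
    for i in range(len(seq) - w + 1):
        count = count_motifs(seq[i : i + w], cfg.motif)
        fraction = count * len(cfg.motif) / w
        if count > 0 and fraction >= cfg.min_motif_fraction:
            hits.append(
                MotifWindow(
                    start_offset=i + 1,
                    end_offset=i + w,
                    motif_count=count,
                    motif_fraction=fraction,
                )
            )
    hits.sort(key=lambda h: (-h.motif_count, h.start_offset))
    return hits
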