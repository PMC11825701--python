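"""Readers and writers for every external format the pipeline touches.

Dialects handled here, once:

* GTF — 1-based inclusive coordinates, ``gene_id``/``transcript_id``
  attributes (parsed with :mod:`gffutils`).
* FASTA — genome sequences (Biopython).
* BED6 — CAGE peak intervals, 0-based half-open.
* STAR ``SJ.out.tab`` — 9 whitespace-separated columns, intron coordinates
  1-based inclusive first/last intronic base.
* TSV/JSON reports — deterministic column and row order.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    ConfigError,
    GenomicInterval,
    IsoforgeError,
    JunctionCountTable,
    ReferenceIndex,
    SJRecord,
    TranscriptModel,
    ValidationError,
)

PathLike = Union[str, Path]


class FormatError(IsoforgeError):
    """Malformed input file (names the file and, where known, the line)."""


_SJ_STRAND = {0: None, 1: "+", 2: "-"}
_SJ_STRAND_CODE = {None: 0, "+": 1, "-": 2}


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _gtf_db(path: PathLike) -> gffutils.FeatureDB:
    try:
        return gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise FormatError(f"malformed GTF {path}: {exc}") from exc


def read_transcripts_gtf(
    path: PathLike, support: Optional[Mapping[str, Mapping[str, int]]] = None
) -> list[TranscriptModel]:
    """Read exon features from a GTF into validated transcript models.

    ``support`` optionally maps transcript_id -> {sample -> count}; models for
    transcripts absent from the mapping carry ``support=None``.
    """
    db = _gtf_db(path)
    exons: dict[str, list[GenomicInterval]] = {}
    gene_of: dict[str, str] = {}
    order: list[str] = []
    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        try:
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes["gene_id"][0]
        except KeyError as exc:
            raise FormatError(
                f"{path}: exon at {feat.seqid}:{feat.start}-{feat.end} missing "
                f"{exc} attribute"
            ) from exc
        if feat.strand not in ("+", "-"):
            raise FormatError(
                f"{path}: exon of transcript {tid} lacks a defined strand"
            )
        if tid not in exons:
            order.append(tid)
            gene_of[tid] = gid
            exons[tid] = []
        elif gene_of[tid] != gid:
            raise ValidationError(
                f"{path}: transcript {tid} assigned to multiple genes "
                f"({gene_of[tid]}, {gid})"
            )
        # GTF is 1-based inclusive; internal is 0-based half-open.
        exons[tid].append(
            GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        )
    models = []
    for tid in order:
        ivs = sorted(exons[tid], key=lambda e: e.start)
        sup = dict(support[tid]) if support and tid in support else None
        try:
            models.append(
                TranscriptModel(
                    transcript_id=tid, gene_id=gene_of[tid], exons=tuple(ivs),
                    support=sup,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc}") from exc
    return models


def read_annotation_gtf(path: PathLike) -> ReferenceIndex:
    """Read a reference annotation GTF and build the novelty index."""
    models = read_transcripts_gtf(path)
    genes: dict[str, list[TranscriptModel]] = {}
    for m in models:
        genes.setdefault(m.gene_id, []).append(m)
    return ReferenceIndex(genes)


def write_transcripts_gtf(
    models: Sequence[TranscriptModel], path: PathLike, source: str = "isoforge"
) -> None:
    """Emit transcript/exon GTF rows, 1-based inclusive, deterministic order."""
    ordered = sorted(models, key=lambda m: (m.chrom, m.start, m.gene_id, m.transcript_id))
    with open(path, "w") as fh:
        for m in ordered:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            fh.write(
                f"{m.chrom}\t{source}\ttranscript\t{m.start + 1}\t{m.end}\t.\t"
                f"{m.strand}\t.\t{attrs}\n"
            )
            for e in m.exons:
                fh.write(
                    f"{m.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{m.strand}\t.\t{attrs}\n"
                )


def write_annotation_gtf(index: ReferenceIndex, path: PathLike) -> None:
    write_transcripts_gtf(list(index.transcripts.values()), path)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_genome_fasta(path: PathLike) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_genome_fasta(genome: Mapping[str, Union[str, bytearray]], path: PathLike) -> None:
    records = [
        SeqRecord(Seq(str(seq) if not isinstance(seq, (bytes, bytearray)) else seq.decode()),
                  id=name, description="")
        for name, seq in sorted(genome.items())
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# BED6 (CAGE peaks)
# ---------------------------------------------------------------------------

def read_cage_bed(path: PathLike) -> list[GenomicInterval]:
    peaks: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED row with <3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "+"
            peaks.append(GenomicInterval(chrom, start, end, strand))
    return peaks


def write_cage_bed(peaks: Sequence[GenomicInterval], path: PathLike) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(sorted(peaks, key=lambda x: (x.chrom, x.start))):
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak{i + 1}\t0\t{p.strand}\n")


# ---------------------------------------------------------------------------
# STAR SJ.out.tab
# ---------------------------------------------------------------------------

def read_sj_table(path: PathLike, sample_id: Optional[str] = None) -> JunctionCountTable:
    """Load a 9-column STAR splice-junction table.

    Columns: chrom, intron start (1-based), intron end (1-based, inclusive),
    strand code {0,1,2}, motif code, annotated flag, unique reads, multi
    reads, max overhang. Internally the intron becomes 0-based half-open.
    """
    sample = sample_id if sample_id is not None else Path(path).name.split(".")[0]
    table = JunctionCountTable(sample_id=sample)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 columns, found {len(fields)}"
                )
            chrom = fields[0]
            try:
                start1, end1, strand_code, motif, annotated, uniq, multi, overhang = (
                    int(fields[1]), int(fields[2]), int(fields[3]), int(fields[4]),
                    int(fields[5]), int(fields[6]), int(fields[7]), int(fields[8]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field: {exc}") from exc
            if uniq < 0 or multi < 0:
                raise ValidationError(f"{path}:{lineno}: negative read count")
            if start1 > end1:
                raise ValidationError(
                    f"{path}:{lineno}: intron start {start1} > end {end1}"
                )
            if strand_code not in _SJ_STRAND:
                raise FormatError(f"{path}:{lineno}: bad strand code {strand_code}")
            table.add(
                SJRecord(
                    chrom=chrom,
                    start=start1 - 1,
                    end=end1,
                    strand=_SJ_STRAND[strand_code],
                    motif=motif,
                    annotated=bool(annotated),
                    unique_reads=uniq,
                    multi_reads=multi,
                    max_overhang=overhang,
                )
            )
    return table


def write_sj_table(table: JunctionCountTable, path: PathLike) -> None:
    with open(path, "w") as fh:
        for (chrom, start, end), rec in sorted(table.records.items()):
            fh.write(
                f"{chrom}\t{start + 1}\t{end}\t{_SJ_STRAND_CODE[rec.strand]}\t"
                f"{rec.motif}\t{int(rec.annotated)}\t{rec.unique_reads}\t"
                f"{rec.multi_reads}\t{rec.max_overhang}\n"
            )


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _record_to_dict(record) -> dict:
    if is_dataclass(record) and not isinstance(record, type):
        return asdict(record)
    if isinstance(record, Mapping):
        return dict(record)
    raise TypeError(f"cannot serialize record of type {type(record)!r}")


def records_to_frame(records: Iterable) -> pd.DataFrame:
    rows = [_record_to_dict(r) for r in records]
    if not rows:
        return pd.DataFrame()
    return pd.DataFrame(rows, columns=list(rows[0].keys()))


def write_report(
    records,
    path: PathLike,
    fmt: str = "tsv",
    columns: Optional[Sequence[str]] = None,
    header_comment: Optional[str] = None,
) -> None:
    """Write pipeline records as TSV (default) or JSON with stable columns."""
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = records_to_frame(records)
    if columns is not None:
        frame = frame.reindex(columns=list(columns))
    if fmt == "tsv":
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            frame.to_csv(fh, sep="\t", index=False)
    elif fmt == "json":
        payload = frame.to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)
            fh.write("\n")
    else:
        raise ConfigError(f"unknown report format {fmt!r} (use 'tsv' or 'json')")


def read_report(path: PathLike, fmt: str = "tsv") -> pd.DataFrame:
    if fmt == "tsv":
        return pd.read_csv(path, sep="\t", comment="#")
    if fmt == "json":
        with open(path) as fh:
            return pd.DataFrame(json.load(fh))
    raise ConfigError(f"unknown report format {fmt!r} (use 'tsv' or 'json')")
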