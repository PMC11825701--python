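"""Independent brute-force oracles used to cross-check the implementation.

Everything here recomputes expected answers by exhaustive enumeration over
the raw reference transcript models, deliberately avoiding the package's
index structures and classification code paths.
"""

from __future__ import annotations

import numpy as np

from isoforge.model import GenomicInterval, ReferenceIndex, TranscriptModel


def oracle_category(model: TranscriptModel, index: ReferenceIndex) -> str:
    """Structural category by exhaustive chain/sub-chain/site enumeration."""
    refs = [m for ms in index.genes.values() for m in ms]

    def exonic_overlap(a: TranscriptModel, b: TranscriptModel) -> int:
        total = 0
        for ea in a.exons:
            for eb in b.exons:
                if ea.chrom == eb.chrom:
                    total += max(0, min(ea.end, eb.end) - max(ea.start, eb.start))
        return total

    # gene assignment: same-strand gene with maximal exonic overlap
    per_gene: dict[str, int] = {}
    for gene_id, models in index.genes.items():
        ov = sum(
            exonic_overlap(model, r) for r in models if r.strand == model.strand
        )
        if ov > 0:
            per_gene[gene_id] = ov
    if len(per_gene) > 1:
        spans = {}
        for g in per_gene:
            ms = index.genes[g]
            spans[g] = (min(m.start for m in ms), max(m.end for m in ms))
        for g1 in per_gene:
            for g2 in per_gene:
                if g1 < g2:
                    a, b = spans[g1], spans[g2]
                    if a[1] <= b[0] or b[1] <= a[0]:
                        return "fusion_like"
    if not per_gene:
        opposite = any(
            exonic_overlap(model, r) > 0
            for r in refs
            if r.strand != model.strand and r.chrom == model.chrom
        )
        return "antisense" if opposite else "intergenic"

    chain = model.junctions
    if not chain:
        for r in refs:
            if (
                r.n_exons == 1
                and r.chrom == model.chrom
                and r.strand == model.strand
                and r.start <= model.start
                and model.end <= r.end
            ):
                return "FSM"
        return "genic"

    same = [
        r
        for r in refs
        if r.chrom == model.chrom and r.strand == model.strand and r.junctions
    ]
    for r in same:
        if r.junctions == chain:
            return "FSM"
    n = len(chain)
    for r in same:
        rj = r.junctions
        for i in range(len(rj) - n + 1):
            if rj[i : i + n] == chain:
                return "ISM"
    donors, acceptors = set(), set()
    for r in same:
        for a, b in r.junctions:
            if r.strand == "+":
                donors.add(a)
                acceptors.add(b)
            else:
                donors.add(b)
                acceptors.add(a)
    for a, b in chain:
        d, ac = (a, b) if model.strand == "+" else (b, a)
        if d not in donors or ac not in acceptors:
            return "NNC"
    return "NIC"


def oracle_cryptic_exons(model: TranscriptModel, gene_id: str, index: ReferenceIndex):
    """Strict intron-derived-exon calls by full containment enumeration."""
    hits = []
    ref_exons = [e for m in index.genes[gene_id] for e in m.exons]
    for i in range(1, model.n_exons - 1):
        exon = model.exons[i]
        if any(
            exon.start < re.end and re.start < exon.end for re in ref_exons
        ):
            continue
        for host in index.genes[gene_id]:
            introns = host.introns
            for gi, intron in enumerate(introns):
                if not (intron.start < exon.start and exon.end < intron.end):
                    continue
                if (
                    model.junctions[i - 1][0] == intron.start
                    and model.junctions[i][1] == intron.end
                ):
                    idx = gi + 1 if host.strand == "+" else len(introns) - gi
                    hits.append((exon.start, exon.end, host.transcript_id, idx))
    return sorted(hits)


def random_query_models(reference, index: ReferenceIndex, n: int, seed: int):
    """Random transcript models exercising every structural category."""
    rng = np.random.default_rng(seed)
    refs = [m for ms in index.genes.values() for m in ms]
    multi = [r for r in refs if r.n_exons >= 4]
    chrom_len = len(next(iter(reference.genome.values())))
    out = []
    for i in range(n):
        r = multi[int(rng.integers(len(multi)))]
        exons = [list((e.start, e.end)) for e in r.exons]
        kind = rng.choice(
            ["fsm", "ism", "skip", "merge", "shift", "mono", "anti", "gap"]
        )
        strand = r.strand
        if kind == "fsm":
            exons[0][0] = max(0, exons[0][0] - int(rng.integers(0, 40)))
            exons[-1][1] += int(rng.integers(0, 40))
        elif kind == "ism":
            lo = int(rng.integers(0, len(exons) - 1))
            hi = int(rng.integers(lo + 2, len(exons) + 1))
            exons = exons[lo:hi]
        elif kind == "skip":
            k = int(rng.integers(1, len(exons) - 1))
            exons = exons[:k] + exons[k + 1 :]
        elif kind == "merge":
            k = int(rng.integers(0, len(exons) - 1))
            exons = exons[:k] + [[exons[k][0], exons[k + 1][1]]] + exons[k + 2 :]
        elif kind == "shift":
            k = int(rng.integers(1, len(exons)))
            exons[k][0] += int(rng.integers(1, 7))  # novel acceptor/donor site
        elif kind == "mono":
            e = exons[int(rng.integers(len(exons)))]
            exons = [[e[0], e[1]]]
        elif kind == "anti":
            e = exons[int(rng.integers(len(exons)))]
            exons = [[e[0], e[1]]]
            strand = "-" if strand == "+" else "+"
        else:  # gap: an interval far from any gene
            pos = chrom_len + 1000 + 200 * i
            exons = [[pos, pos + 150]]
        model = TranscriptModel(
            transcript_id=f"q{i}",
            gene_id="",
            exons=tuple(
                GenomicInterval(r.chrom, a, b, strand) for a, b in exons
            ),
        )
        out.append(model)
    return out
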