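# Methods

## Coordinates and formats

All internal coordinates are 0-based half-open on the genome's forward
strand. GTF I/O converts 1-based inclusive coordinates at the boundary;
STAR `SJ.out.tab` intron coordinates (1-based first/last intronic base)
likewise. A junction is stored as the intron it spans,
`(upstream_exon.end, downstream_exon.start)`; donor and acceptor are
resolved strand-aware. SJ rows with STAR strand code 0 (undetermined) match
event junctions by coordinates alone — the source data do not say how such
rows should be handled, and discarding them would silently lose unstranded
libraries' reads.

## Structural classification

Multi-exon categories are a function of the splice chain only; transcript
ends never change a multi-exon category (a property the tests assert).
`ISM` requires a *contiguous* junction sub-chain, matching the
5′/3′-degradation interpretation of truncated isoforms; non-contiguous
subsets (e.g. exon skipping) fall to `NIC`/`NNC` by site membership. When
several reference transcripts share an FSM chain, the match minimizes total
end distance, then lexicographic transcript id. Mono-exon queries are `FSM`
only when contained (tolerance 0, configurable in code) in a same-strand
reference mono-exon transcript. Gene assignment is maximal same-strand
exonic overlap; a query overlapping two genes whose spans are disjoint is
`fusion_like` and excluded downstream — fusion calling itself is out of
scope. Known/novel re-annotation maps `FSM` to known and everything else to
novel; the known set is a parameter because the treatment of `ISM` is a
judgment call in the field.

Strict cryptic-exon calls require (i) an internal exon strictly inside a
reference intron of the assigned gene, (ii) no overlap with any reference
exon of that gene, and (iii) flanking query junctions that reuse the host
intron's donor and acceptor. Relaxed mode drops (iii). Strict calls are
provably a subset of relaxed calls.

## ORF and NMD

The ORF is the longest ATG-initiated open reading frame with an in-frame
stop (ties: 5′-most; minimum 30 aa, configurable). NMD features are
computed in transcript space: the PTC flag applies the 50-nt rule with
strict inequality (a stop exactly 50 nt upstream of the last junction is
not flagged); `long_utr3_nt` defaults to 350 and `short_orf_aa` to 100;
upstream ORFs are ATG-initiated ORFs of ≥ 10 aa entirely within the 5′UTR.
These thresholds are tool conventions, not published values, and all live in
`NmdConfig`.

The consequence cascade runs in fixed priority: identical genomic CDS →
`unchanged_ORF`; NAGNAG; no/short ORF → `short_ORF`; any NMD feature →
`PTC_NMD`; else `protein_coding_novel`. Short ORFs outrank NMD features
because unproductive transcripts typically carry several features at once
and the shortest description is kept. The NAGNAG rule is operational: same
genomic stop codon, junction chains identical except one acceptor shifted by
exactly 3 nt, and proteins related by a one-residue N-terminal
indel/substitution after the initiator methionine. The reference ORF is the
matched transcript for FSM/ISM and otherwise the gene's longest-CDS
transcript (ties: lexicographic id).

## Event quantification

The supporting-read ratio is `mean(inc_up, inc_down) / (mean + exc)` over
unique reads; a sum-based variant is available (`ratio_mode="sum"`). The
mean-based form is used because a read pair spanning the cassette supports
both inclusion junctions, so averaging avoids double-counting relative to
the single exclusion junction. Presence requires ≥ 2 unique reads on *each*
inclusion junction (configurable); prevalence is therefore monotone
non-increasing in the threshold, and cohort prevalence should be read as a
function of that threshold rather than a single number. Relative ratios
divide by the baseline group's mean (baseline mean of relative ratios is 1
by construction); two groups are compared with a two-sided Welch t.

The UGG scanner slides a 14-nt window (ESRP-binding motif scale) over the
sense intronic sequence downstream of a cassette's 3′ end, scoring
overlapping TGG occurrences; windows at ≥ 50% motif content are ranked by
count, ties to the 5′-most. Offsets are 1-based from the first intronic
base.

## Abundance, diversity, saturation

Within-gene transcript proportions are per sample; gene-samples with zero
total are flagged undefined and excluded from the abundance filter. The
abundant flag is inclusive at the 40% threshold. Saturation thins each
transcript's read count with Binomial(count, f) at fractions
0.1/0.3/0.5/0.7/0.9/1.0 (20 replicates), detects at ≥ 3 reads (the same
support threshold as structural filtering, for consistency), and fits
`N(f) = Nmax(1 − e^{−λf})` by least squares; the saturation point is
`ln(20)/λ`, where the fitted curve reaches 95% of its asymptote. A
Michaelis–Menten form is available by config. The functional form is a
modeling choice — the detection probability of a Poisson-distributed count
under thinning is not exactly exponential — and the asymptote, not the
curve shape, is the quantity the tests hold to account (recovery within 5%
at 10× the support threshold). Saturation counts transcripts, not genes.

## The synthetic-data generator

The generator emulates: multi-exon coding genes with canonical GT/AG
introns on both strands; derived isoforms differing from their parent by
exactly one event (exon skip, cryptic exon, intron retention, 5′/3′
truncation, NAGNAG acceptor shift, UTR-only extension, PTC-bearing donor
shift); CAGE peaks at annotated TSSs; AATAAA planted 20 nt from transcript
3′ ends; and junction tables drawn per sample as N ~ Poisson(depth),
I ~ Binomial(N, ψ), with both inclusion junctions receiving the identical
count I (a cassette-spanning read pair supports both; an independent-jitter
option exists, default off) and the exclusion junction N − I. Defaults:
12 genes, 6–9 exons of 90–180 nt, introns 120–260 nt, 6 samples,
depth 200 junction reads/event/sample, ψ = 0.3 — per-event junction depths
of this order are what a deeply sequenced short-read cohort yields at a
moderately expressed locus, and ψ = 0.3 is a mid-range inclusion level that
leaves both junction classes well observed.

Two deliberate conventions make planted truth labels *exactly* recoverable,
so label-recovery tests are meaningful at 100%:

* **T-free coding alphabet.** Outside planted start/stop codons (and the
  worked example's peptide cassette), exonic sequence uses only A/C/G.
  Every ATG and every stop codon contains a T, so the planted ORF is the
  unique ATG-initiated, stop-terminated ORF in any reading frame; no random
  sequence can outgrow it. Real transcriptomes obviously contain competing
  ORFs — passing these tests shows the classifiers implement their rules
  exactly, not that ORF choice is unambiguous on real data.
* **Phase-0 architecture.** Exon 1 is pure 5′UTR, the start codon occupies
  the last 3 nt of exon 2, all exon lengths are multiples of 3, and the stop
  codon sits in the final exon ahead of a 60-nt 3′UTR. Every junction then
  has reading-frame phase 0, so any in-frame cassette contributes whole
  codons and every event kind has a constructible, guaranteed consequence
  class. The intron upstream of exon 3 ends in `CAGCAG`, a tandem NAGNAG
  acceptor.

Intron retention is only emitted when the retained sequence guarantees its
label: the first in-frame stop must exist inside the intron, leave a prefix
ORF that is both ≥ 100 aa and longer than everything downstream, and sit
> 50 nt upstream of the final junction; otherwise the event is infeasible
for that gene. The PTC event extends an exon 6 nt into its intron with a
planted `GTA TAA` (the parent intron keeps its GT), creating a novel donor
and a guaranteed PTC.

The ERBB2-like fixture is a 27-exon gene on the plus strand with a 102-nt
cassette planted inside intron 14. Its 34-codon translation is 8 synthetic
residues + the 19-mer `SLPRIKLGGGPRGRGHRDW` + 7 synthetic residues: only
the 19-mer is sequence-faithful (it is the immunogen peptide minus its
N-terminal conjugation cysteine); the 15 flanking residues are placeholders,
as the full cassette peptide is not printed anywhere. Downstream of the
cassette, offsets 47–60 carry `GGTGGTGGTGGTGG` with TGG-free flanks. The
phase of the repeat matters: its four TGG occurrences end exactly at offset
60 and begin at 49, so the 5′-most window containing all four is exactly
47–60 under the rank-by-score-then-5′-most rule; a repeat starting with TGG
at 47 would tie with windows beginning at 45 and 46 and misplace the
reported window.

What the generator does **not** emulate: sequencing error, reverse-
transcription and intra-priming artifacts, expression overdispersion beyond
Poisson, multi-isoform reference genes, overlapping genes, alternative
polyadenylation clusters, and realistic codon usage (see the T-free
convention). Tests passing on these fixtures certify the computations, not
robustness to those real-data phenomena.

## Pipeline and reproducibility

One seed drives every stochastic stage; rerunning with the same config and
seed reproduces byte-identical outputs (asserted in tests). Every output
table carries the run's config hash (SHA-256 over the analytic config,
excluding the output path) in a header comment; the manifest records seed,
version, and per-stage record counts. Problem sizes in the default test and
acceptance runs (8–12 genes, 200–400 planted events, 500-sample estimator
calibration at depth 10⁴) were chosen as the smallest sizes at which the
binomial standard errors make the calibration assertions sharp.

## Known limitations

* The structural classifier assumes the reference index fits in memory and
  searches ISM candidates linearly per chromosome/strand; atlas-scale
  references would want an interval/suffix index over chains.
* `fusion_like` is a label, not a fusion caller.
* The NAGNAG detector requires the 3-nt acceptor-shift signature; tandem
  donors (GTNGT) are not modeled.
* uORF counting requires the transcript sequence; when a caller supplies
  only exon structure, the count is 0 rather than unknown.
* Saturation extrapolates a parametric curve; it will understate Nmax when
  the read-count distribution is heavily overdispersed.
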