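"""Cryptic-exon event quantification, cohort prevalence, relative ratios,
and the UGG-rich window scanner."""

import numpy as np
import pytest

from isoforge.event import (
    EventDef,
    MotifConfig,
    PresenceRule,
    cohort_prevalence,
    count_motifs,
    event_from_cryptic_call,
    quantify_event,
    relative_support_ratio,
    scan_ugg_rich,
)
from isoforge.model import ConfigError, IsoforgeError, JunctionCountTable, SJRecord
from isoforge.structural import classify_transcript, detect_intron_derived_exons


EVENT = EventDef(
    name="e1", chrom="chr1", strand="+",
    inclusion_up=(1000, 1500), inclusion_down=(1602, 2000),
    exclusion=(1000, 2000),
)


def table(sample, inc_up=0, inc_down=0, exc=0, extra=()):
    t = JunctionCountTable(sample_id=sample)
    rows = [
        ("chr1", *EVENT.inclusion_up, inc_up),
        ("chr1", *EVENT.inclusion_down, inc_down),
        ("chr1", *EVENT.exclusion, exc),
        *extra,
    ]
    for chrom, a, b, count in rows:
        t.add(SJRecord(chrom=chrom, start=a, end=b, strand="+", unique_reads=count))
    return t


class TestEventDef:
    def test_exclusion_must_span_inclusions(self):
        with pytest.raises(ConfigError):
            EventDef(
                name="bad", chrom="chr1", strand="+",
                inclusion_up=(1000, 1500), inclusion_down=(1602, 2000),
                exclusion=(1000, 1900),
            )

    def test_derived_from_strict_cryptic_call_matches_host_intron(self, erbb2):
        call = classify_transcript(erbb2.isoform, erbb2.index)
        ce = detect_intron_derived_exons(erbb2.isoform, call, erbb2.index)[0]
        event = event_from_cryptic_call(ce, erbb2.index)
        intron14 = erbb2.parent.introns[13]
        assert event.exclusion == (intron14.start, intron14.end)
        assert event.inclusion_up[0] == event.exclusion[0]
        assert event.inclusion_down[1] == event.exclusion[1]
        assert (
            event.inclusion_up, event.inclusion_down, event.exclusion
        ) == (
            erbb2.event.inclusion_up, erbb2.event.inclusion_down, erbb2.event.exclusion
        )

    def test_relaxed_mode_call_is_rejected(self, erbb2):
        call = classify_transcript(erbb2.isoform, erbb2.index)
        ce = detect_intron_derived_exons(
            erbb2.isoform, call, erbb2.index, mode="relaxed"
        )[0]
        with pytest.raises(ConfigError):
            event_from_cryptic_call(ce, erbb2.index)


class TestQuantifyEvent:
    def test_ratio_arithmetic(self):
        q = quantify_event(EVENT, table("s", 10, 10, 30))
        assert q.ratio == pytest.approx(0.25)
        assert q.present

    def test_all_zero_counts_is_undefined_and_absent(self):
        q = quantify_event(EVENT, table("s"))
        assert q.ratio is None and not q.present

    def test_sum_mode_ratio(self):
        q = quantify_event(EVENT, table("s", 10, 10, 30), ratio_mode="sum")
        assert q.ratio == pytest.approx(20 / 50)

    def test_invariant_to_unrelated_junctions_and_row_order(self):
        base = quantify_event(EVENT, table("s", 5, 5, 15))
        noisy = table(
            "s", 5, 5, 15,
            extra=[("chr1", 9000, 9400, 99), ("chr2", 1000, 2000, 50)],
        )
        q = quantify_event(EVENT, noisy)
        assert (q.inc_up, q.inc_down, q.exc, q.ratio) == (
            base.inc_up, base.inc_down, base.exc, base.ratio,
        )

    def test_missing_junctions_count_as_zero(self):
        t = JunctionCountTable(sample_id="s")
        t.add(SJRecord(chrom="chr1", start=1000, end=1500, strand="+", unique_reads=4))
        q = quantify_event(EVENT, t)
        assert (q.inc_up, q.inc_down, q.exc) == (4, 0, 0)
        assert q.ratio == pytest.approx(1.0)


class TestPrevalence:
    def test_psi_zero_cohort_has_zero_prevalence(self):
        tables = [table(f"s{i}", 0, 0, 40) for i in range(10)]
        prevalence, _ = cohort_prevalence(EVENT, tables)
        assert prevalence == 0.0

    def test_five_of_twenty_present_is_a_quarter(self):
        tables = [
            table(f"s{i}", 3, 3, 10) if i < 5 else table(f"s{i}", 1, 1, 20)
            for i in range(20)
        ]
        prevalence, quants = cohort_prevalence(EVENT, tables, PresenceRule(2))
        assert prevalence == pytest.approx(0.25)
        assert sum(q.present for q in quants) == 5

    def test_raising_threshold_never_raises_prevalence(self):
        rng = np.random.default_rng(4)
        tables = [
            table(f"s{i}", int(rng.integers(0, 6)), int(rng.integers(0, 6)), 10)
            for i in range(30)
        ]
        prev = [
            cohort_prevalence(EVENT, tables, PresenceRule(t))[0] for t in (1, 2, 3, 4)
        ]
        assert all(a >= b for a, b in zip(prev, prev[1:]))

    def test_duplicate_sample_id_is_an_error(self):
        with pytest.raises(IsoforgeError, match="duplicate"):
            cohort_prevalence(EVENT, [table("s", 1, 1, 1), table("s", 2, 2, 2)])


class TestRelativeSupportRatio:
    def test_identical_samples_give_unit_ratios_and_zero_t(self):
        quants = [quantify_event(EVENT, table(f"s{i}", 5, 5, 15)) for i in range(10)]
        labels = {f"s{i}": ("ctrl" if i < 5 else "case") for i in range(10)}
        res = relative_support_ratio(quants, labels, "ctrl")
        assert np.allclose(res.per_sample["relative_ratio"], 1.0)
        assert res.t_statistic == 0.0

    def test_baseline_group_mean_is_one_by_construction(self):
        rng = np.random.default_rng(5)
        quants = [
            quantify_event(
                EVENT,
                table(f"s{i}", int(rng.integers(1, 20)), int(rng.integers(1, 20)), 25),
            )
            for i in range(12)
        ]
        labels = {f"s{i}": ("ctrl" if i % 2 else "case") for i in range(12)}
        res = relative_support_ratio(quants, labels, "ctrl")
        assert res.group_means["ctrl"] == pytest.approx(1.0)

    def test_group_ordering_tracks_inclusion_levels(self):
        """Two groups simulated at psi 0.05 vs 0.30 (n=5, depth 5000): the
        high-inclusion group's mean relative ratio exceeds the baseline's in
        essentially every replicate."""
        from isoforge.simulate import SimConfig

        rng = np.random.default_rng(6)
        wins = 0
        n_rep = 200
        for _ in range(n_rep):
            quants = []
            labels = {}
            for i in range(10):
                psi = 0.05 if i < 5 else 0.30
                n = rng.poisson(5000)
                inc = rng.binomial(n, psi)
                quants.append(
                    quantify_event(EVENT, table(f"s{i}", inc, inc, n - inc))
                )
                labels[f"s{i}"] = "ctrl" if i < 5 else "resistant"
            res = relative_support_ratio(quants, labels, "ctrl")
            if res.group_means["resistant"] > res.group_means["ctrl"]:
                wins += 1
        assert wins / n_rep >= 0.99

    def test_empty_or_zero_baseline_is_an_error(self):
        quants = [quantify_event(EVENT, table("s0", 0, 0, 10))]
        with pytest.raises(ConfigError):
            relative_support_ratio(quants, {"s0": "a"}, "missing")


class TestUggScanner:
    def test_planted_window_at_47_to_60_ranks_first(self, erbb2):
        hits = scan_ugg_rich(erbb2.downstream_intron_seq)
        top = hits[0]
        assert (top.start_offset, top.end_offset) == (47, 60)
        assert top.end_offset - top.start_offset + 1 == 14
        assert top.motif_count == 4

    def test_motif_free_sequence_yields_nothing(self):
        assert scan_ugg_rich("ACACACACACACACACACAC") == []

    def test_sequence_shorter_than_window_yields_nothing(self):
        assert scan_ugg_rich("TGGTGG") == []

    def test_overlapping_occurrences_are_counted(self):
        assert count_motifs("TGGTGGTGG", "TGG") == 3
        assert count_motifs("AAAA", "AA") == 3

    def test_ranking_matches_exhaustive_enumeration_oracle(self):
        rng = np.random.default_rng(12)
        cfg = MotifConfig(min_motif_fraction=0.2)
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), size=80))
            hits = scan_ugg_rich(seq, cfg)
            oracle = []
            for i in range(len(seq) - 14 + 1):
                window = seq[i : i + 14]
                count = sum(
                    1 for j in range(12) if window[j : j + 3] == "TGG"
                )
                if count > 0 and count * 3 / 14 >= 0.2:
                    oracle.append((-count, i + 1))
            oracle.sort()
            assert [(-h.motif_count, h.start_offset) for h in hits] == oracle

    def test_deleting_the_top_window_removes_it(self, erbb2):
        """Sequence-level mirror of the 14-bp deletion experiment: excising
        the UGG-rich window abolishes the top-ranked hit."""
        seq = erbb2.downstream_intron_seq
        top = scan_ugg_rich(seq)[0]
        deleted = seq[: top.start_offset - 1] + seq[top.end_offset :]
        remaining = scan_ugg_rich(deleted)
        assert all(h.motif_count < top.motif_count for h in remaining)
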