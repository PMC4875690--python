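"""Read QC: each filtering rule, trimming, dedup, and idempotence."""

import pytest

from cnvpop.readqc import (
    FormatError,
    PairingError,
    ReadRecord,
    adapter_match,
    deduplicate,
    qc_pairs,
    qc_read,
    trim_low_quality,
)


def read(seq, quals=None, id_="r1"):
    if quals is None:
        quals = [30] * len(seq)
    elif isinstance(quals, int):
        quals = [quals] * len(seq)
    return ReadRecord(id=id_, sequence=seq, qualities=quals)


def test_length_mismatch_is_a_format_error():
    with pytest.raises(FormatError):
        ReadRecord(id="x", sequence="ACGT", qualities=[30, 30])


class TestQcRules:
    def test_n_fraction_at_threshold_discards(self):
        # 10 N in 100 bases is exactly 10% -> discarded (>= rule)
        r = read("N" * 10 + "A" * 90)
        assert qc_read(r) == ("discard", "N fraction")

    def test_n_fraction_below_threshold_kept(self):
        r = read("N" * 9 + "A" * 91)
        decision, kept = qc_read(r)
        assert decision == "keep" and kept.sequence == r.sequence

    def test_clean_read_kept_untrimmed(self):
        r = read("A" * 100)
        decision, kept = qc_read(r)
        assert decision == "keep"
        assert kept.sequence == r.sequence and kept.qualities == r.qualities

    def test_low_quality_fraction_strictly_above_65pct_discards(self):
        r_bad = read("A" * 100, [7] * 66 + [30] * 34)
        assert qc_read(r_bad) == ("discard", "low quality")
        # exactly 65% low-quality bases, interleaved so no 3-run triggers
        # the trimming rule: kept by the strict > reading
        quals = [7, 7, 30] * 32 + [7, 30, 30, 30]
        assert sum(q <= 7 for q in quals) == 65 and len(quals) == 100
        assert qc_read(read("A" * 100, quals))[0] == "keep"

    def test_adapter_match_needs_more_than_10_aligned_bases(self):
        adapter = "AGATCGGAAGAGC"  # 13 bp
        r = read("C" * 40 + adapter + "C" * 47)
        assert qc_read(r, [adapter]) == ("discard", "adapter")
        # an 11-base overlap with 2 mismatches still matches...
        assert adapter_match("T" * 50 + adapter[:9] + "GG", [adapter][0])
        # ...but a 10-base overlap does not, however perfect
        assert not adapter_match("T" * 60 + adapter[:10], adapter)
        # and 3 mismatches never match
        mutated = adapter[:4] + "TTT" + adapter[7:]
        assert not adapter_match("C" * 30 + mutated + "C" * 30, adapter)

    def test_trim_at_first_low_quality_run_then_length_filter(self):
        # Phred <= 13 at positions 10-12 (0-based): prefix of 10 kept -> too short
        quals = [30] * 10 + [13, 12, 11] + [30] * 47
        r = read("A" * 60, quals)
        assert qc_read(r) == ("discard", "short after trim")
        trimmed = trim_low_quality(r)
        assert len(trimmed.sequence) == 10

    def test_trim_keeps_long_enough_prefix(self):
        quals = [30] * 50 + [10, 10, 10] + [30] * 7
        r = read("A" * 60, quals)
        decision, kept = qc_read(r)
        assert decision == "keep"
        assert len(kept.sequence) == 50

    def test_two_low_quality_bases_do_not_trigger_trim(self):
        quals = [30] * 20 + [10, 10] + [30] * 38
        decision, kept = qc_read(read("A" * 60, quals))
        assert decision == "keep" and len(kept.sequence) == 60


class TestDeduplicate:
    def pair(self, s1, s2, id_="p"):
        return (read(s1, id_=id_ + "/1"), read(s2, id_=id_ + "/2"))

    def test_identical_pairs_collapse_to_first(self):
        pairs = [self.pair("ACGT" * 15, "TTTT" * 15)] * 2
        kept, dropped = deduplicate(pairs)
        assert len(kept) == 1 and dropped == 1

    def test_one_base_difference_keeps_both(self):
        a = self.pair("ACGT" * 15, "TTTT" * 15)
        b = self.pair("ACGT" * 15, "TTTA" * 15)
        kept, dropped = deduplicate([a, b])
        assert len(kept) == 2 and dropped == 0

    def test_five_copies_plus_three_unique_keeps_four(self):
        copies = [self.pair("A" * 60, "C" * 60)] * 5
        unique = [
            self.pair("G" * 60, "C" * 60),
            self.pair("A" * 60, "G" * 60),
            self.pair("T" * 60, "C" * 60),
        ]
        kept, dropped = deduplicate(copies + unique)
        assert len(kept) == 4 and dropped == 4


def test_qc_pairs_counts_balance_and_idempotence():
    pairs = [
        (read("A" * 100, id_="a/1"), read("C" * 100, id_="a/2")),  # clean
        (read("N" * 20 + "A" * 80, id_="b/1"), read("C" * 100, id_="b/2")),  # N-frac
        (read("A" * 100, id_="c/1"), read("C" * 100, [7] * 80 + [30] * 20, id_="c/2")),
        (read("A" * 100, id_="d/1"), read("C" * 100, id_="d/2")),  # dup of a
    ]
    kept, report = qc_pairs(pairs)
    assert report.n_input == 8
    assert report.discarded["N fraction"] == 1
    assert report.discarded["low quality"] == 1
    assert report.discarded["mate discarded"] == 2
    assert report.discarded["duplicate"] == 2
    assert report.n_kept + sum(report.discarded.values()) == report.n_input
    assert report.n_kept == 2
    assert len(kept) == 1
    # qc of already-clean output changes nothing
    kept2, report2 = qc_pairs(kept)
    assert kept2 == kept
    assert report2.n_kept == report2.n_input


def test_orphan_mates_raise():
    with pytest.raises(PairingError):
        qc_pairs([(read("A" * 60, id_="x/1"), read("C" * 60, id_="y/2"))])


def test_discard_counts_order_independent_for_rules_1_to_3():
    reads = [
        read("N" * 50 + "A" * 50),
        read("A" * 100, [5] * 100),
        read("A" * 100),
    ]
    reasons = sorted(qc_read(r)[1] if qc_read(r)[0] == "discard" else "keep" for r in reads)
    reasons_rev = sorted(
        qc_read(r)[1] if qc_read(r)[0] == "discard" else "keep" for r in reversed(reads)
    )
    assert reasons == reasons_rev == ["N fraction", "keep", "low quality"]
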