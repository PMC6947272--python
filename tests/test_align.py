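"""Alignment, demultiplexing, error statistics and depth profiles."""

import itertools
import random

import numpy as np
import pytest

from nanoamp.align import (
    AlignmentError,
    ReadAlignment,
    align_read,
    align_to_panel,
    assign_amplicon,
    demultiplex,
    depth_profile,
    error_stats,
    _largest_remainder_percent,
    reverse_complement,
)
from nanoamp.panel import Panel
from nanoamp.simulate import ErrorProfile, SimSample, simulate_reads


def oracle_score(ref, read, match=2, mismatch=-3, go=-4, ge=-1, ov=-1):
    """Exhaustive DP oracle for the glocal convention (read overhangs at
    ``ov`` per base, reference paid end to end)."""
    m, n = len(ref), len(read)
    NEG = -(10 ** 8)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]
    for j in range(n + 1):
        H[0][j] = ov * j
    for i in range(1, m + 1):
        Y[i][0] = go + (i - 1) * ge
        H[i][0] = Y[i][0]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            sm = H[i - 1][j - 1] + (match if ref[i - 1] == read[j - 1] else mismatch)
            Y[i][j] = max(H[i - 1][j] + go, Y[i - 1][j] + ge)
            X[i][j] = max(H[i][j - 1] + go, X[i][j - 1] + ge)
            H[i][j] = max(sm, Y[i][j], X[i][j])
    return max(H[m][j] + ov * (n - j) for j in range(n + 1))


class TestAlignRead:
    def test_identical_sequences(self):
        a = align_read("ACGTACGT", "ACGTACGT")
        assert a.ops == [("match", 8, "")]
        assert a.score == 16
        assert a.ref_start == 1 and a.read_start == 1

    def test_single_deletion_forced(self):
        a = align_read("ACGACGT", "ACGTACGT")
        assert a.ops == [("match", 3, ""), ("del", 1, ""), ("match", 4, "")]

    def test_single_insertion_recorded_with_sequence(self):
        a = align_read("ACGTTTACG", "ACGTACG")
        assert ("ins", 2, "TT") in a.ops

    def test_adjacent_gap_cheaper_than_split_gaps(self):
        # deleting "GG" as one event costs -5; two separated 1-bp gaps -8
        a = align_read("ACTAACTA", "ACTGGAACTA")
        dels = [op for op in a.ops if op[0] == "del"]
        assert dels == [("del", 2, "")]
        assert a.score == 8 * 2 - 5

    def test_mismatch_run_carries_read_bases(self):
        a = align_read("ACCTACGT", "ACGTACGT")
        assert ("mismatch", 1, "C") in a.ops

    def test_empty_sequence_rejected(self):
        with pytest.raises(AlignmentError):
            align_read("", "ACGT")

    def test_read_overhang_is_cheap_not_free(self):
        clean = align_read("ACGTACGT", "ACGTACGT")
        tagged = align_read("GGGG" + "ACGTACGT", "ACGTACGT")
        assert tagged.ops == clean.ops
        assert tagged.score == clean.score - 4

    def test_matches_oracle_on_all_short_pairs(self):
        alphabet = "AC"
        for la, lb in [(1, 1), (2, 3), (3, 3), (4, 4), (5, 4)]:
            for ref in map("".join, itertools.product(alphabet, repeat=la)):
                for read in map("".join, itertools.product(alphabet, repeat=lb)):
                    assert align_read(read, ref).score == oracle_score(ref, read), (
                        ref, read)

    def test_matches_oracle_on_random_longer_pairs(self):
        rng = random.Random(23)
        for _ in range(300):
            ref = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 12)))
            read = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 12)))
            assert align_read(read, ref).score == oracle_score(ref, read), (ref, read)

    def test_indels_left_normalized(self):
        # deletion in a homopolymer run must sit at the leftmost position
        a = align_read("ACGGGT", "ACGGGGT")
        pos = a.ref_start
        for op, length, _ in a.ops:
            if op == "del":
                break
            pos += length
        assert pos == 3  # first G of the run

    def test_alignment_span_invariants(self):
        a = align_read("ACGTTTACG", "ACGTACG")
        assert a.ref_span == sum(
            l for op, l, _ in a.ops if op in ("match", "mismatch", "del"))
        assert a.read_span == sum(
            l for op, l, _ in a.ops if op in ("match", "mismatch", "ins"))


class TestDemultiplex:
    BARCODES = {"s1": "ACGTACGTACGT", "s2": "TTTTGGGGCCCC"}

    def test_exact_prefix_assigned_and_trimmed(self):
        assigned, un = demultiplex(
            [("r1", "ACGTACGTACGT" + "AAAA")], self.BARCODES)
        assert [r[0] for r in assigned["s1"]] == ["r1"]
        assert assigned["s1"][0][1] == "AAAA"
        assert not un

    def test_one_substitution_still_assigned(self):
        assigned, un = demultiplex(
            [("r1", "ACGAACGTACGT" + "AAAA")], self.BARCODES)
        assert [r[0] for r in assigned["s1"]] == ["r1"]

    def test_too_many_edits_unassigned(self):
        assigned, un = demultiplex(
            [("r1", "GGGGGGGGGGGG" + "AAAA")], self.BARCODES, max_edits=3)
        assert [r[0] for r in un] == ["r1"]

    def test_equidistant_tie_unassigned(self):
        barcodes = {"s1": "AAAA", "s2": "TTTT"}
        assigned, un = demultiplex([("r1", "AATT" + "CCCC")], barcodes, max_edits=3)
        assert [r[0] for r in un] == ["r1"]

    def test_reverse_orientation_normalized(self):
        payload = "ACGTACGTACGT" + "AACCGGTTAACC"
        assigned, _ = demultiplex(
            [("r1", reverse_complement(payload))], self.BARCODES)
        assert assigned["s1"][0][1] == "AACCGGTTAACC"

    def test_duplicate_barcodes_rejected(self):
        with pytest.raises(AlignmentError):
            demultiplex([], {"s1": "AAAA", "s2": "AAAA"})


class TestAssignAmplicon:
    def test_exact_reference_assigned(self, panel):
        ref = panel["CEBPA_ex1"].reference_seq
        assert assign_amplicon(ref, panel) == "CEBPA_ex1"

    def test_random_sequence_unassigned(self, panel):
        rng = random.Random(9)
        junk = "".join(rng.choice("ACGT") for _ in range(400))
        assert assign_amplicon(junk, panel) is None

    def test_corrupted_read_still_assigned(self, panel, profiles):
        sub = Panel([panel["FLT3_ex14-15"]])
        s = SimSample("s", "", depth_per_amplicon=5)
        res = simulate_reads(sub, [s], profiles, seed=31)
        for _, seq in res.reads:
            assert assign_amplicon(seq, panel) == "FLT3_ex14-15"


class TestErrorStats:
    def test_zero_noise_is_all_identity(self, panel):
        ref = panel["FLT3_ex20"].reference_seq
        alns = [align_read(ref, ref, read_id=f"r{i}", amplicon="FLT3_ex20")
                for i in range(3)]
        st = error_stats(alns)
        assert st.as_tuple() == (100.0, 0.0, 0.0, 0.0)

    def test_percentages_sum_to_exactly_100(self, panel, profiles):
        sub = Panel([panel["FLT3_ex20"]])
        s = SimSample("s", "", depth_per_amplicon=40)
        res = simulate_reads(sub, [s], profiles, seed=13)
        ref = panel["FLT3_ex20"].reference_seq
        alns = [align_read(seq, ref, read_id=rid, amplicon="FLT3_ex20")
                for rid, seq in res.reads]
        st = error_stats(alns)
        assert sum(st.as_tuple()) == pytest.approx(100.0, abs=1e-9)

    def test_largest_remainder_rounding(self):
        assert sum(_largest_remainder_percent([1, 1, 1])) == pytest.approx(100.0)
        assert _largest_remainder_percent([997, 1, 1, 1]) == [99.7, 0.1, 0.1, 0.1]

    def test_empty_input_rejected(self):
        with pytest.raises(AlignmentError):
            error_stats([])

    def test_simulated_profile_recovery(self, panel, profiles):
        """Estimated rates from 600 reads track the generating profile."""
        sub = Panel([panel["NPM1_ex11"]])
        s = SimSample("s", "", depth_per_amplicon=600)
        res = simulate_reads(sub, [s], profiles, seed=21)
        ref = panel["NPM1_ex11"].reference_seq
        alns = [align_read(seq, ref, read_id=rid, amplicon="NPM1_ex11")
                for rid, seq in res.reads]
        st = error_stats(alns)
        p = profiles["NPM1_ex11"]
        assert abs(st.identical_pct - p.identity_rate) <= 0.75
        assert abs(st.ins_pct - p.ins_rate) <= 0.5
        assert abs(st.del_pct - p.del_rate) <= 0.5
        assert abs(st.sub_pct - p.sub_rate) <= 0.5


class TestDepthProfile:
    def test_full_length_perfect_reads(self, panel):
        amp = panel["FLT3_ex20"]
        alns = [align_read(amp.reference_seq, amp.reference_seq,
                           read_id=f"r{i}", amplicon=amp.name) for i in range(7)]
        prof = depth_profile(alns, amp, floor=5)
        assert (prof.depth == 7).all()
        assert not prof.any_low

    def test_position_below_floor_flagged(self, panel):
        amp = panel["FLT3_ex20"]
        alns = [align_read(amp.reference_seq, amp.reference_seq,
                           read_id=f"r{i}", amplicon=amp.name) for i in range(49)]
        prof = depth_profile(alns, amp, floor=50)
        assert prof.any_low
        assert len(prof.low_positions) == amp.length

    def test_no_alignments_all_zero(self, panel):
        amp = panel["FLT3_ex20"]
        prof = depth_profile([], amp)
        assert prof.depth.sum() == 0
        assert prof.any_low
        assert prof.summary()["max"] == 0.0

    def test_partial_read_covers_its_span_only(self, panel):
        amp = panel["FLT3_ex20"]
        ref = amp.reference_seq
        alns = [align_read(ref[50:120], ref, read_id="r", amplicon=amp.name)]
        prof = depth_profile(alns, amp, floor=1)
        assert prof.depth[55] == 1 and prof.depth[10] == 0


def test_align_to_panel_routes_reads(panel, profiles):
    sub = Panel([panel["NPM1_ex11"], panel["FLT3_ex20"]])
    samples = [SimSample("s", "", depth_per_amplicon=10)]
    res = simulate_reads(sub, samples, profiles, seed=8)
    per_amp, un = align_to_panel(res.reads, sub)
    assert len(per_amp["NPM1_ex11"]) == 10
    assert len(per_amp["FLT3_ex20"]) == 10
    assert not un
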