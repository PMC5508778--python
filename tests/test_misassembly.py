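"""Physical coverage, low-coverage interval search and contig breaking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from hicscaffold import Contig, ContigSet, break_contigs, find_low_coverage_interval, physical_coverage
from hicscaffold.core import BreakCall
from hicscaffold.misassembly import (
    PhysicalCoverageProfile,
    coverage_from_spans,
    detect_breaks,
    pair_span,
)

from conftest import make_pair


def brute_force_coverage(length, spans):
    cov = np.zeros(length, dtype=int)
    for lo, hi in spans:
        for i in range(lo, hi):
            cov[i] += 1
    return cov


def brute_force_min_subarray(arr, delta):
    """Exhaustive O(n^2) search over all subarrays of (arr - delta)."""
    shifted = [v - delta for v in arr]
    best = (0, 0, float("inf"))
    for i in range(len(shifted)):
        total = 0.0
        for j in range(i, len(shifted)):
            total += shifted[j]
            if total < best[2]:
                best = (i, j + 1, total)
    return best


class TestPhysicalCoverage:
    def test_gap_between_mates_is_covered(self):
        contig = Contig("c", 100)
        pair = make_pair("c", 0, "c", 90, read_len=10)
        prof = physical_coverage([pair], contig)
        assert prof.coverage.tolist() == [1] * 100

    def test_no_pairs_gives_zero_profile(self):
        prof = physical_coverage([], Contig("c", 50))
        assert prof.coverage.tolist() == [0] * 50

    def test_identical_pairs_add(self):
        contig = Contig("c", 40)
        pair = make_pair("c", 10, "c", 10, read_len=10)
        prof = physical_coverage([pair, pair], contig)
        expected = [0] * 10 + [2] * 10 + [0] * 20
        assert prof.coverage.tolist() == expected

    def test_pair_on_other_contig_raises(self):
        with pytest.raises(ValueError, match="other"):
            physical_coverage([make_pair("other", 0)], Contig("c", 100))

    def test_matches_brute_force_painting(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            length = int(rng.integers(10, 300))
            n = int(rng.integers(0, 50))
            spans, pairs = [], []
            for k in range(n):
                lo = int(rng.integers(0, length - 2))
                hi = int(rng.integers(lo + 1, length + 1))
                spans.append((lo, hi))
                pairs.append(
                    make_pair("c", lo, "c", hi - 1, read_len=1, read_id=f"r{k}")
                )
            prof = physical_coverage(pairs, Contig("c", length))
            assert prof.coverage.tolist() == brute_force_coverage(length, spans).tolist()


class TestLowCoverageInterval:
    def test_flat_dip_is_found(self):
        prof = PhysicalCoverageProfile("c", np.array([5, 5, 0, 0, 5, 5]))
        call = find_low_coverage_interval(prof, delta=3)
        assert (call.start, call.end, call.score) == (2, 4, -6)

    def test_no_call_when_coverage_meets_delta(self):
        prof = PhysicalCoverageProfile("c", np.array([3, 4, 5, 3]))
        assert find_low_coverage_interval(prof, delta=3) is None

    def test_all_zero_flags_whole_contig(self):
        prof = PhysicalCoverageProfile("c", np.array([0, 0, 0]))
        call = find_low_coverage_interval(prof, delta=2)
        assert (call.start, call.end, call.score) == (0, 3, -6)

    def test_empty_profile_raises(self):
        with pytest.raises(ValueError, match="empty"):
            find_low_coverage_interval(PhysicalCoverageProfile("c", np.array([])), 1.0)

    @given(
        arr=hnp.arrays(np.int64, st.integers(1, 200), elements=st.integers(0, 20)),
        delta=st.integers(1, 15),
    )
    @settings(deadline=None, derandomize=True, max_examples=150)
    def test_agrees_with_exhaustive_subarray_search(self, arr, delta):
        prof = PhysicalCoverageProfile("c", arr)
        call = find_low_coverage_interval(prof, float(delta))
        i, j, total = brute_force_min_subarray(arr.tolist(), delta)
        if total >= 0:
            assert call is None
        else:
            assert call.score == pytest.approx(total)
            # the optimum may not be unique; the returned interval must
            # achieve the optimal deficit
            assert sum(v - delta for v in arr[call.start : call.end]) == pytest.approx(total)


class TestBreakContigs:
    def contig(self, name="c", length=100_000):
        return ContigSet([Contig(name, length, "A" * length)])

    def test_midpoint_split(self):
        out, remap = break_contigs(
            self.contig(), [BreakCall("c", 49_000, 51_000, -500.0)]
        )
        assert [(c.name, c.length) for c in out] == [("c_1", 50_000), ("c_2", 50_000)]
        assert remap.map("c", 0) == ("c_1", 0)
        assert remap.map("c", 50_000) == ("c_2", 0)
        assert remap.map("c", 99_999) == ("c_2", 49_999)

    def test_shallow_call_is_ignored(self):
        out, remap = break_contigs(
            self.contig(), [BreakCall("c", 49_000, 51_000, -5.0)], min_score_magnitude=100.0
        )
        assert [c.name for c in out] == ["c"]
        assert remap.pieces == {}

    def test_two_calls_split_into_three_pieces(self):
        calls = [
            BreakCall("c", 24_000, 26_000, -900.0),  # deeper: applied first
            BreakCall("c", 74_000, 76_000, -400.0),
        ]
        out, _ = break_contigs(self.contig(), calls)
        assert [(c.name, c.length) for c in out] == [
            ("c_1", 25_000),
            ("c_2_1", 50_000),
            ("c_2_2", 25_000),
        ]

    def test_edge_margin_rejects_near_end_calls(self):
        out, _ = break_contigs(
            self.contig(), [BreakCall("c", 0, 4000, -900.0)], edge_margin=10_000
        )
        assert [c.name for c in out] == ["c"]

    def test_sequence_is_partitioned(self):
        seq = "".join("ACGT"[i % 4] for i in range(1000))
        contigs = ContigSet([Contig("c", 1000, seq)])
        out, _ = break_contigs(contigs, [BreakCall("c", 400, 600, -100.0)])
        assert out["c_1"].sequence + out["c_2"].sequence == seq

    @given(
        length=st.integers(1000, 50_000),
        mids=st.lists(st.integers(100, 49_000), max_size=4),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_total_bases_conserved(self, length, mids):
        contigs = ContigSet([Contig("c", length)])
        calls = [
            BreakCall("c", max(m - 50, 0), min(m + 50, length), -float(i + 1))
            for i, m in enumerate(mids)
            if m + 50 <= length
        ]
        out, _ = break_contigs(contigs, calls)
        assert out.total_bases() == length


class TestDetectBreaks:
    def test_chimeric_junction_recovered_and_clean_contig_untouched(self):
        rng = np.random.default_rng(5)
        length, junction = 120_000, 70_000
        spans = []
        # dense pair spans within each true segment, none across the junction
        for lo_bound, hi_bound in ((0, junction), (junction, length)):
            for _ in range(3000):
                lo = int(rng.integers(lo_bound, hi_bound - 600))
                span = int(rng.exponential(800)) + 200
                spans.append((lo, min(lo + span, hi_bound)))
        pairs = [
            make_pair("c", lo, "c", hi - 1, read_len=1, read_id=f"r{i}")
            for i, (lo, hi) in enumerate(spans)
        ]
        calls = detect_breaks(
            Contig("c", length), pairs, min_drop_span=200, edge_margin=5000
        )
        assert len(calls) == 1
        assert abs(calls[0].midpoint - junction) < 2000

        # the same pair density without a junction yields no call
        spans2 = []
        for _ in range(6000):
            lo = int(rng.integers(0, length - 600))
            span = int(rng.exponential(800)) + 200
            spans2.append((lo, min(lo + span, length)))
        pairs2 = [
            make_pair("c", lo, "c", hi - 1, read_len=1, read_id=f"s{i}")
            for i, (lo, hi) in enumerate(spans2)
        ]
        assert detect_breaks(Contig("c", length), pairs2, min_drop_span=200, edge_margin=5000) == []


def test_pair_span_covers_both_mates_and_gap():
    assert pair_span(make_pair("c", 30, "c", 5, read_len=10)) == (5, 40)


def test_coverage_from_spans_handles_adjacent_spans():
    cov = coverage_from_spans(6, [(0, 3), (3, 6)])
    assert cov.tolist() == [1, 1, 1, 1, 1, 1]
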