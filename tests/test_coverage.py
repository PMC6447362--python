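"""Bedgraph coverage tracks: parsing, querying, totals, round-trips."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metachip import CoverageTrack, GenomicInterval, read_bedgraph, track_total, write_bedgraph
from metachip.coverage import BedgraphFormatError

from conftest import dense_of, make_track


@st.composite
def step_lists(draw):
    """Random valid non-overlapping step lists with exactly-representable values."""
    n = draw(st.integers(0, 12))
    steps, pos = [], 0
    for _ in range(n):
        pos += draw(st.integers(0, 5))
        length = draw(st.integers(1, 8))
        value = draw(st.integers(0, 20)) / 2.0
        steps.append((pos, pos + length, value))
        pos += length
    return steps


class TestReadBedgraph:
    def test_single_line_semantics(self):
        track = read_bedgraph(io.StringIO("chr1\t0\t10\t2.0\n"))
        values, mean = track.query(GenomicInterval("chr1", 0, 10))
        assert list(values) == [2.0] * 10 and mean == 2.0

    def test_overlap_is_format_error_with_line_number(self):
        text = "chr1\t0\t10\t1\nchr1\t5\t15\t1\n"
        with pytest.raises(BedgraphFormatError, match="line 2"):
            read_bedgraph(io.StringIO(text))

    def test_negative_value_rejected(self):
        with pytest.raises(BedgraphFormatError, match="negative"):
            read_bedgraph(io.StringIO("chr1\t0\t10\t-1\n"))

    def test_gap_counts_as_zero(self):
        track = read_bedgraph(io.StringIO("chr1\t0\t10\t2\nchr1\t20\t30\t4\n"))
        values, mean = track.query(GenomicInterval("chr1", 0, 30))
        # brute force: (10*2 + 10*0 + 10*4) / 30
        assert mean == pytest.approx(2.0)
        assert list(values[10:20]) == [0.0] * 10

    def test_zero_rows_and_headers_accepted(self):
        text = "track type=bedGraph\nbrowser position chr1\nchr1\t0\t5\t0\nchr1\t5\t8\t3\n"
        track = read_bedgraph(io.StringIO(text))
        assert track.total_signal() == 9.0

    def test_unsorted_input_is_sorted(self):
        track = read_bedgraph(io.StringIO("chr1\t20\t30\t4\nchr1\t0\t10\t2\n"))
        assert track.query(GenomicInterval("chr1", 0, 10))[1] == 2.0


class TestQuery:
    def test_stepped_track_partial_overlap(self):
        track = make_track([(0, 4, 1.0), (4, 8, 3.0)])
        values, mean = track.query(GenomicInterval("chr1", 2, 6))
        assert list(values) == [1, 1, 3, 3] and mean == 2.0

    def test_unknown_chromosome_returns_zeros_with_flag(self):
        track = make_track([(0, 10, 2.0)], chrom="chr2")
        values, mean = track.query(GenomicInterval("chr3", 0, 5))
        assert mean == 0.0 and not values.any()
        assert track.last_query_missing_chrom
        track.query(GenomicInterval("chr2", 0, 5))
        assert not track.last_query_missing_chrom

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(step_lists(), st.integers(0, 60), st.integers(1, 30))
    def test_query_matches_per_base_oracle(self, steps, start, length):
        track = make_track(steps)
        dense = dense_of(steps, 200)
        iv = GenomicInterval("chr1", start, start + length)
        values, mean = track.query(iv)
        expected = dense[start : start + length]
        assert np.array_equal(values, expected)
        assert mean == expected.mean()
        means = track.interval_means("chr1", [start], [start + length])
        assert means[0] == expected.mean()


class TestWriteBedgraph:
    def test_equal_adjacent_steps_merged(self):
        track = make_track([(0, 5, 1.0), (5, 10, 1.0)])
        buf = io.StringIO()
        write_bedgraph(track, buf)
        assert buf.getvalue() == "chr1\t0\t10\t1\n"

    def test_empty_track_empty_output(self):
        buf = io.StringIO()
        write_bedgraph(CoverageTrack(), buf)
        assert buf.getvalue() == ""

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(step_lists())
    def test_round_trip_per_base_identity(self, steps):
        track = make_track(steps)
        buf = io.StringIO()
        write_bedgraph(track, buf)
        again = read_bedgraph(io.StringIO(buf.getvalue()))
        dense = dense_of(steps, 200)
        if dense.any():
            got, _ = again.query(GenomicInterval("chr1", 0, 200))
            assert np.array_equal(got, dense)
        assert again.total_signal() == track.total_signal()

    def test_declared_reads_survive_round_trip(self):
        track = make_track([(0, 10, 2.0)], total_mapped_reads=12345)
        buf = io.StringIO()
        write_bedgraph(track, buf)
        assert read_bedgraph(io.StringIO(buf.getvalue())).total_mapped_reads == 12345


class TestTrackTotal:
    def test_closed_form(self):
        assert track_total(make_track([(0, 10, 2.0)])).total_signal == 20.0

    def test_empty_track(self):
        assert track_total(CoverageTrack()).total_signal == 0.0

    def test_additivity_over_concatenation(self, rng):
        a = [(0, 10, 2.0), (15, 20, 1.0)]
        b = [(100, 130, 3.0)]
        total_ab = track_total(make_track(a + b)).total_signal
        assert total_ab == track_total(make_track(a)).total_signal + track_total(make_track(b)).total_signal

    def test_split_step_invariance(self):
        whole = make_track([(0, 10, 2.5)])
        split = make_track([(0, 4, 2.5), (4, 10, 2.5)])
        assert track_total(whole).total_signal == track_total(split).total_signal

    def test_scaling_scales_total_and_means(self):
        track = make_track([(0, 10, 2.0), (20, 30, 4.0)])
        scaled = track.scaled(3.0)
        assert scaled.total_signal() == 3.0 * track.total_signal()
        iv = GenomicInterval("chr1", 5, 25)
        assert scaled.query(iv)[1] == 3.0 * track.query(iv)[1]

    def test_normaliser_prefers_declared_reads(self):
        declared = track_total(make_track([(0, 100, 5.0)], total_mapped_reads=10), read_length_bp=50)
        assert declared.normaliser == 10 and declared.basis == "declared_reads"
        proxy = track_total(make_track([(0, 100, 5.0)]), read_length_bp=50)
        assert proxy.normaliser == 500.0 / 50 and proxy.basis == "signal_over_read_length"
        bases = track_total(make_track([(0, 100, 5.0)]), basis="bases")
        assert bases.normaliser == 500.0
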