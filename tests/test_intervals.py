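"""Interval model, BED/bedGraph round-trips, merging and coverage quantification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rosyn.errors import ParseError, ValidationError
from rosyn.intervals import (
    CoverageTrack,
    GenomicInterval,
    Peak,
    interval_signal,
    read_bed,
    read_bedgraph,
    sort_and_merge,
    write_bed,
    write_bedgraph,
)
from helpers import make_peaks


class TestGenomicInterval:
    def test_valid_interval(self):
        iv = GenomicInterval("chr1", 100, 200)
        assert iv.length == 100
        assert iv.midpoint == 150

    @pytest.mark.parametrize("start,end", [(100, 90), (100, 100), (-1, 50)])
    def test_invalid_coordinates_rejected(self, start, end):
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", start, end)

    def test_whitespace_chrom_rejected(self):
        with pytest.raises(ValidationError):
            GenomicInterval("chr 1", 0, 10)


class TestBedIO:
    def test_bed3_line_maps_to_peak(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\n")
        peaks = read_bed(p, "bed3")
        assert peaks[0].interval == GenomicInterval("chr1", 100, 200)
        assert peaks[0].name == "peak_1"
        assert peaks[0].score == 0

    def test_inverted_coordinates_rejected(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t90\n")
        with pytest.raises(ValidationError):
            read_bed(p, "bed3")

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\nchr1\txx\t300\n")
        with pytest.raises(ParseError, match=":2"):
            read_bed(p, "bed3")

    def test_bed6_round_trip_is_exact(self, tmp_path):
        src = tmp_path / "in.bed"
        src.write_text(
            "chr1\t100\t200\talpha\t5\t.\n"
            "chr2\t0\t50\tbeta\t0\t.\n"
            "chr2\t75\t80\tgamma\t1000\t.\n"
        )
        peaks = read_bed(src, "bed6")
        dst = tmp_path / "out.bed"
        write_bed(peaks, dst)
        assert dst.read_text() == src.read_text()

    def test_duplicate_names_rejected(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t1\t2\tx\t0\t.\nchr1\t5\t6\tx\t0\t.\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_bed(p, "bed6")

    def test_narrowpeak_score_column(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        line = "chr1\t10\t60\tpk1\t850\t.\t12.5\t30.1\t25.2\t25\n"
        p.write_text(line)
        peaks = read_bed(p, "narrowPeak")
        assert peaks[0].score == 850


class TestBedGraph:
    def test_read_two_steps(self, tmp_path):
        p = tmp_path / "a.bg"
        p.write_text("chr1\t0\t10\t1.0\nchr1\t10\t20\t3.0\n")
        track = read_bedgraph(p)
        assert len(track) == 2
        assert track.total_signal() == pytest.approx(40.0)

    def test_overlapping_steps_rejected(self, tmp_path):
        p = tmp_path / "a.bg"
        p.write_text("chr1\t0\t10\t1.0\nchr1\t5\t15\t1.0\n")
        with pytest.raises(ValidationError, match="overlap"):
            read_bedgraph(p)

    def test_negative_value_rejected(self, tmp_path):
        p = tmp_path / "a.bg"
        p.write_text("chr1\t0\t10\t-1.0\n")
        with pytest.raises(ValidationError):
            read_bedgraph(p)

    def test_empty_file_gives_empty_track(self, tmp_path):
        p = tmp_path / "a.bg"
        p.write_text("")
        track = read_bedgraph(p)
        assert len(track) == 0
        assert track.total_signal() == 0.0

    def test_round_trip_preserves_values(self, tmp_path, simple_track):
        p = tmp_path / "a.bg"
        write_bedgraph(simple_track, p)
        again = read_bedgraph(p)
        assert list(again.steps()) == list(simple_track.steps())


class TestSortAndMerge:
    def test_stitch_example(self):
        peaks = make_peaks([(100, 200), (5000, 5100), (20000, 20100)])
        merged = sort_and_merge(peaks, 12500)
        assert [(iv.start, iv.end) for iv, _ in merged] == [(100, 5100), (20000, 20100)]
        assert [len(names) for _, names in merged] == [2, 1]

    def test_single_peak_identity(self):
        merged = sort_and_merge(make_peaks([(10, 20)]), 12500)
        assert [(iv.start, iv.end) for iv, _ in merged] == [(10, 20)]

    def test_touching_peaks_merge_at_gap_zero(self):
        merged = sort_and_merge(make_peaks([(0, 10), (10, 20)]), 0)
        assert [(iv.start, iv.end) for iv, _ in merged] == [(0, 20)]

    def test_gap_just_above_max_does_not_merge(self):
        merged = sort_and_merge(make_peaks([(0, 10), (12511, 12520)]), 12500)
        assert len(merged) == 2

    def test_negative_gap_rejected(self):
        with pytest.raises(ValidationError):
            sort_and_merge([], -1)

    @staticmethod
    def _oracle(peaks, max_gap):
        """O(n^2) repeated pairwise merging until fixpoint."""
        items = [
            [p.interval.chrom, p.interval.start, p.interval.end, {p.name}] for p in peaks
        ]
        changed = True
        while changed:
            changed = False
            for i in range(len(items)):
                for j in range(i + 1, len(items)):
                    a, b = items[i], items[j]
                    if a[0] != b[0]:
                        continue
                    gap = max(a[1], b[1]) - min(a[2], b[2])
                    if gap <= max_gap:
                        items[i] = [a[0], min(a[1], b[1]), max(a[2], b[2]), a[3] | b[3]]
                        del items[j]
                        changed = True
                        break
                if changed:
                    break
        return sorted((c, s, e, frozenset(n)) for c, s, e, n in items)

    @given(
        spans=st.lists(
            st.tuples(st.integers(0, 60000), st.integers(1, 2000)), min_size=1, max_size=50
        ),
        max_gap=st.sampled_from([0, 100, 12500]),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_exhaustive_merge_oracle(self, spans, max_gap):
        peaks = make_peaks([(s, s + w) for s, w in spans])
        # oracle requires unique names; make_peaks numbers them
        got = sort_and_merge(peaks, max_gap)
        got_norm = sorted(
            (iv.chrom, iv.start, iv.end, frozenset(names)) for iv, names in got
        )
        assert got_norm == self._oracle(peaks, max_gap)

    def test_idempotent(self, rng):
        spans = sorted(rng.integers(0, 100000, size=30))
        peaks = make_peaks([(int(s), int(s) + 500) for s in spans])
        once = sort_and_merge(peaks, 5000)
        as_peaks = [
            Peak(iv, f"m{i}") for i, (iv, _) in enumerate(once)
        ]
        twice = sort_and_merge(as_peaks, 5000)
        assert [(iv.start, iv.end) for iv, _ in once] == [
            (iv.start, iv.end) for iv, _ in twice
        ]


class TestIntervalSignal:
    def test_rectangle_area(self):
        track = CoverageTrack([("chr1", 0, 100, 2.0)])
        assert interval_signal(track, GenomicInterval("chr1", 0, 50)) == 100.0

    def test_partial_overlap_example(self, simple_track):
        # [0,10)=1, [10,20)=3, query [5,15) -> 5*1 + 5*3
        assert interval_signal(simple_track, GenomicInterval("chr1", 5, 15)) == 20.0

    def test_no_overlap_is_zero(self, simple_track):
        assert interval_signal(simple_track, GenomicInterval("chr1", 100, 200)) == 0.0
        assert interval_signal(simple_track, GenomicInterval("chrX", 0, 10)) == 0.0

    @given(
        split=st.integers(1, 9999),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=50, deadline=None)
    def test_additive_over_split_point(self, split, seed):
        r = np.random.default_rng(seed)
        edges = np.unique(r.integers(0, 10000, size=20))
        steps = [
            ("chr1", int(a), int(b), float(r.uniform(0, 5)))
            for a, b in zip(edges[:-1], edges[1:])
        ]
        track = CoverageTrack(steps)
        whole = interval_signal(track, GenomicInterval("chr1", 0, 10000))
        left = interval_signal(track, GenomicInterval("chr1", 0, split)) if split > 0 else 0
        right = interval_signal(track, GenomicInterval("chr1", split, 10000))
        assert whole == pytest.approx(left + right, rel=1e-9, abs=1e-9)

    def test_matches_per_base_sum_oracle(self, rng):
        edges = np.unique(rng.integers(0, 5000, size=30))
        steps = [
            ("chr1", int(a), int(b), float(rng.uniform(0, 3)))
            for a, b in zip(edges[:-1], edges[1:])
            if rng.random() < 0.7
        ]
        track = CoverageTrack(steps)
        per_base = np.zeros(5000)
        for _, s, e, v in track.steps():
            per_base[s:e] = v
        for _ in range(20):
            a, b = sorted(rng.integers(0, 5000, size=2))
            if a == b:
                continue
            iv = GenomicInterval("chr1", int(a), int(b))
            assert interval_signal(track, iv) == pytest.approx(per_base[a:b].sum(), rel=1e-9)
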