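"""Hockey-stick cutoff geometry, super-enhancer calling and gene annotation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rosyn.errors import ValidationError
from rosyn.intervals import CoverageTrack, GeneAnnotation, GenomicInterval, Peak
from rosyn.enhancers import (
    StitchedRegion,
    annotate_nearest_gene,
    call_super_enhancers,
    hockey_stick_cutoff,
    score_regions,
    stitch_peaks,
)
from helpers import make_peaks


class TestHockeyStickCutoff:
    def test_quadratic_curve_tangent_at_half(self):
        # y = x^2 scaled: tangent slope 1 at x = 0.5 -> index 51 of 101, signal 0.25
        s = [((i) / 100) ** 2 for i in range(101)]
        cutoff_signal, cutoff_index, _, _ = hockey_stick_cutoff(s)
        assert cutoff_index == 51
        assert cutoff_signal == pytest.approx(0.25)

    @pytest.mark.parametrize("k", [2, 3, 5])
    @pytest.mark.parametrize("n", [101, 1001])
    def test_power_curve_matches_analytic_tangent_point(self, k, n):
        # for y = x^k the tangent-slope-1 point is x* = k^(-1/(k-1))
        x = np.arange(n) / (n - 1)
        s = x ** k
        cutoff_signal, cutoff_index, _, _ = hockey_stick_cutoff(s)
        x_star = k ** (-1.0 / (k - 1.0))
        assert abs(x[cutoff_index - 1] - x_star) <= 2.0 / (n - 1)

    def test_flat_signals_degenerate(self):
        with pytest.warns(UserWarning, match="flat"):
            cutoff_signal, cutoff_index, _, y = hockey_stick_cutoff([5.0] * 10)
        assert cutoff_signal == 5.0
        assert np.all(y == 0)

    def test_linear_signals_tie_break_to_top(self):
        # diagonal curve: y - x == 0 everywhere; tie-break -> top, zero supers
        s = np.arange(1, 51, dtype=float)
        cutoff_signal, cutoff_index, _, _ = hockey_stick_cutoff(s)
        assert cutoff_index == 50
        assert cutoff_signal == 50.0

    def test_too_few_signals_rejected(self):
        with pytest.raises(ValidationError):
            hockey_stick_cutoff([1.0, 2.0])

    def test_unsorted_rejected(self):
        with pytest.raises(ValidationError):
            hockey_stick_cutoff([3.0, 1.0, 2.0])

    @given(seed=st.integers(0, 2**20), n=st.integers(3, 200))
    @settings(max_examples=200, deadline=None)
    def test_matches_exhaustive_scan_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        s = np.sort(rng.uniform(0, 100, size=n))
        if s[-1] == s[0]:
            return
        _, cutoff_index, _, _ = hockey_stick_cutoff(s)
        # independent exhaustive re-implementation
        best_i, best_d = 0, np.inf
        for i in range(n):
            x = i / (n - 1)
            y = (s[i] - s[0]) / (s[-1] - s[0])
            if y - x <= best_d:  # <= ties toward largest index
                best_i, best_d = i, y - x
        assert cutoff_index == best_i + 1


def _scored_regions(signals):
    return [
        StitchedRegion(GenomicInterval("chr1", 1000 * i, 1000 * i + 500), (f"p{i}",), s)
        for i, s in enumerate(signals)
    ]


class TestCallSuperEnhancers:
    def test_single_outlier_is_the_only_super(self):
        ranking = call_super_enhancers(_scored_regions([1.0] * 99 + [1000.0]))
        assert ranking.n_super == 1
        assert ranking.super_regions[0].signal == 1000.0
        # brute-force check: nothing else lies above the cutoff
        assert all(
            r.signal <= ranking.cutoff_signal for r in ranking.regions[:-1]
        )

    def test_flat_signals_give_zero_supers(self):
        with pytest.warns(UserWarning):
            ranking = call_super_enhancers(_scored_regions([7.0] * 10))
        assert ranking.n_super == 0

    def test_result_invariant_to_input_order(self, rng):
        regions = _scored_regions(list(rng.uniform(1, 50, size=40)))
        a = call_super_enhancers(regions)
        shuffled = list(regions)
        rng.shuffle(shuffled)
        b = call_super_enhancers(shuffled)
        assert [r.interval for r in a.regions] == [r.interval for r in b.regions]
        assert [r.rank for r in a.regions] == [r.rank for r in b.regions]
        assert a.cutoff_signal == b.cutoff_signal

    def test_ranks_ascend_with_signal(self, rng):
        ranking = call_super_enhancers(_scored_regions(list(rng.uniform(0, 10, 25))))
        sigs = [r.signal for r in ranking.regions]
        assert sigs == sorted(sigs)
        assert [r.rank for r in ranking.regions] == list(range(1, 26))

    def test_adding_top_region_never_demotes_clear_supers(self, rng):
        signals = sorted(rng.uniform(1, 10, size=50)) + [200.0, 300.0]
        base = call_super_enhancers(_scored_regions(signals))
        grown = call_super_enhancers(_scored_regions(signals + [400.0]))
        assert grown.n_super >= base.n_super - 1
        for r in grown.regions:
            if r.signal > grown.cutoff_signal:
                assert any(
                    s.interval == r.interval for s in grown.super_regions
                )


class TestStitchAndScore:
    def test_stitch_defaults_to_12500(self):
        peaks = make_peaks([(100, 200), (5000, 5100), (20000, 20100)])
        regions = stitch_peaks(peaks)
        assert len(regions) == 2

    def test_tss_exclusion_removes_contained_peak(self):
        peaks = make_peaks([(900, 1100), (50000, 50100)])
        genes = [GeneAnnotation("G1", "chr1", 1000, "+")]
        regions = stitch_peaks(peaks, tss_exclusion=2500, genes=genes)
        names = [n for r in regions for n in r.constituents]
        assert "p0" not in names and "p1" in names

    def test_score_without_control_is_chip_area(self):
        region = StitchedRegion(GenomicInterval("chr1", 0, 1000), ("p",))
        chip = CoverageTrack([("chr1", 0, 1000, 2.0)])
        scored = score_regions([region], chip)
        assert scored[0].signal == 2000.0

    def test_control_subtraction_and_clamp(self):
        region = StitchedRegion(GenomicInterval("chr1", 0, 1000), ("p",))
        chip = CoverageTrack([("chr1", 0, 1000, 2.0)])
        ctrl_small = CoverageTrack([("chr1", 0, 1000, 0.5)])
        ctrl_big = CoverageTrack([("chr1", 0, 1000, 4.0)])
        assert score_regions([region], chip, ctrl_small)[0].signal == 1500.0
        assert score_regions([region], chip, ctrl_big)[0].signal == 0.0

    def test_negative_control_scale_rejected(self):
        region = StitchedRegion(GenomicInterval("chr1", 0, 1000), ("p",))
        chip = CoverageTrack([("chr1", 0, 1000, 2.0)])
        with pytest.raises(ValidationError):
            score_regions([region], chip, chip, control_scale=-1.0)


class TestAnnotateNearestGene:
    def _ranking(self, *spans):
        regions = [
            StitchedRegion(GenomicInterval("chr1", s, e), (f"p{i}",), float(i + 1))
            for i, (s, e) in enumerate(spans)
        ]
        return call_super_enhancers(regions)

    def test_tss_inside_region_is_nearest(self):
        ranking = self._ranking((150_601_879, 150_630_909), (1000, 2000), (5000, 6000))
        genes = [
            GeneAnnotation("MCL1", "chr1", 150_610_000, "+"),
            GeneAnnotation("FAR", "chr1", 10_000_000, "+"),
        ]
        calls = annotate_nearest_gene(ranking, genes)
        big = [c for c in calls if c.region.interval.start == 150_601_879][0]
        assert big.nearest_gene == "MCL1"
        assert abs(big.tss_distance) < big.region.interval.length / 2

    def test_equidistant_tie_breaks_lexicographically(self):
        ranking = self._ranking((1000, 2000), (30000, 31000), (60000, 61000))
        # midpoint of first region = 1500; genes at 1400 and 1600 equidistant
        genes = [
            GeneAnnotation("ZED", "chr1", 1400, "+"),
            GeneAnnotation("ABLE", "chr1", 1600, "-"),
        ]
        calls = annotate_nearest_gene(ranking, genes)
        first = [c for c in calls if c.region.interval.start == 1000][0]
        assert first.nearest_gene == "ABLE"

    def test_gene_free_chromosome_gets_na(self):
        ranking = self._ranking((1000, 2000), (3000, 4000), (5000, 6000))
        genes = [GeneAnnotation("G", "chr9", 100, "+")]
        calls = annotate_nearest_gene(ranking, genes)
        assert all(c.nearest_gene == "NA" and c.tss_distance is None for c in calls)
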