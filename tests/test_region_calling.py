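"""Background adjustment, gap-constrained clustering, peaks, and ranking."""

import numpy as np
import pytest

from phorcmap.genomics_io import GenomicInterval, PipelineParams, ProbeLayout
from phorcmap.region_calling import (
    AdjustedProfile,
    BoundRegion,
    adjust_profile,
    call_bound_regions,
    define_peak,
    rank_by_strength,
)


def make_adjusted(starts, values, cutoff=0.0, length=25, chrom="c"):
    layout = ProbeLayout([chrom] * len(starts), starts, [length] * len(starts))
    return AdjustedProfile(layout, np.asarray(values, dtype=float), cutoff)


def brute_force_regions(adjusted, params):
    """Independent oracle: enumerate maximal qualifying runs probe by probe."""
    layout = adjusted.layout
    mids = layout.midpoints
    ratios = adjusted.values + adjusted.background_cutoff
    regions = []
    run = []
    order = range(len(layout))

    def flush(run):
        if not run:
            return
        span_start = int(layout.starts[run[0]])
        span_end = int(layout.starts[run[-1]] + layout.lengths[run[-1]])
        if span_end - span_start < params.min_region_bp:
            return
        k = params.peak_features
        best = None
        if len(run) <= k:
            windows = [run]
        else:
            windows = [run[i : i + k] for i in range(len(run) - k + 1)]
        for w in windows:
            mean = sum(ratios[i] for i in w) / len(w)
            if best is None or mean > best[0] + 1e-12:
                best = (mean, w)
        strength, w = best
        peak = GenomicInterval(
            layout.chroms[w[0]],
            int(layout.starts[w[0]]),
            int(layout.starts[w[-1]] + layout.lengths[w[-1]]),
        )
        regions.append(
            BoundRegion(
                GenomicInterval(layout.chroms[run[0]], span_start, span_end),
                peak,
                strength,
                len(run),
            )
        )

    for i in order:
        if adjusted.values[i] <= 0:
            continue
        if run and (
            layout.chroms[i] != layout.chroms[run[-1]]
            or mids[i] - mids[run[-1]] > params.max_gap_bp
        ):
            flush(run)
            run = []
        run.append(i)
    flush(run)
    return regions


class TestAdjustProfile:
    def test_constant_profile_adjusts_to_zero(self):
        adj = adjust_profile(np.full(5, 2.0))
        np.testing.assert_array_equal(adj.values, 0.0)
        assert adj.background_cutoff == pytest.approx(2.0)

    def test_sample_sd_cutoff(self):
        # values [1,1,1,1,6]: mean 2, sample SD sqrt(5), cutoff ~ 8.708
        adj = adjust_profile(np.array([1.0, 1, 1, 1, 6]))
        assert adj.background_cutoff == pytest.approx(2 + 3 * np.sqrt(5))
        np.testing.assert_array_equal(adj.values, 0.0)

    def test_value_just_above_cutoff_keeps_excess(self):
        values = np.full(20, 1.0)
        base = adjust_profile(values)
        delta = 0.25
        values2 = values.copy()
        values2[7] = base.background_cutoff + delta
        adj = adjust_profile(values2, cutoff_values=values)
        assert adj.values[7] == pytest.approx(delta)
        assert adj.values.sum() == pytest.approx(delta)

    def test_undefined_values_become_zero_and_need_two_defined(self):
        adj = adjust_profile(np.array([1.0, np.nan, 3.0]))
        assert adj.values[1] == 0.0
        with pytest.raises(ValueError):
            adjust_profile(np.array([np.nan, np.nan, 1.0]))

    def test_population_sd_available(self):
        values = np.array([1.0, 1, 1, 1, 6])
        adj = adjust_profile(values, ddof=0)
        assert adj.background_cutoff == pytest.approx(2 + 3 * values.std(ddof=0))


class TestCallBoundRegions:
    def test_all_zero_profile_yields_no_regions(self):
        adj = make_adjusted(np.arange(0, 360, 36), np.zeros(10), cutoff=1.0)
        assert call_bound_regions(adj) == []

    def test_min_region_length_filter(self):
        # 25-mers at 0,100,200: span [0, 225) = 225 bp < 360 -> dropped
        short = make_adjusted([0, 100, 200], [1.0, 1.0, 1.0], cutoff=1.0)
        assert call_bound_regions(short) == []
        # probes at 800..1200: span [800, 1225) = 425 bp -> one region
        long = make_adjusted([800, 900, 1000, 1100, 1200], np.ones(5), cutoff=1.0)
        (region,) = call_bound_regions(long)
        assert (region.span.start, region.span.end) == (800, 1225)
        assert region.n_features == 5

    def test_gap_rule_splits_clusters(self):
        # two positive probes 600 bp apart: two clusters, both length-filtered
        adj = make_adjusted([0, 600], [1.0, 1.0], cutoff=1.0)
        assert call_bound_regions(adj) == []
        # with relaxed min length they appear as two regions
        regions = call_bound_regions(adj, min_region_bp=10)
        assert len(regions) == 2

    def test_matches_brute_force_oracle_on_random_profiles(self, params):
        rng = np.random.default_rng(7)
        for _ in range(60):
            n = int(rng.integers(3, 80))
            starts = np.sort(rng.choice(np.arange(0, 6000, 36), size=n, replace=False))
            values = np.where(rng.random(n) < 0.4, rng.lognormal(0, 1, n), 0.0)
            adj = make_adjusted(starts, values, cutoff=float(rng.uniform(0.5, 2)))
            got = call_bound_regions(adj, params)
            want = brute_force_regions(adj, params)
            assert got == want

    def test_raising_sd_multiplier_never_adds_regions(self, layout_factory, params):
        rng = np.random.default_rng(8)
        values = rng.lognormal(0, 0.5, 300)
        values[100:130] += 5.0
        layout = layout_factory(300)
        counts = []
        for mult in (0.0, 1.0, 2.0, 3.0, 4.0):
            adj = adjust_profile(values, sd_multiplier=mult)
            adj = AdjustedProfile(layout, adj.values, adj.background_cutoff)
            counts.append(len(call_bound_regions(adj, params)))
        assert counts == sorted(counts, reverse=True)


class TestDefinePeak:
    def test_region_with_k_probes_is_its_own_peak(self):
        starts = np.arange(0, 6 * 36, 36)
        ratios = [2.0, 3, 4, 5, 6, 7]
        peak, strength = define_peak(starts, [25] * 6, ratios, k=6)
        assert (peak.start, peak.end) == (0, 5 * 36 + 25)
        assert strength == pytest.approx(np.mean(ratios))

    def test_best_six_window_selected(self):
        # means of the four 6-windows: 6.5, 7.83, 9.0, 7.83 -> probes 3..8
        ratios = [1, 2, 9, 9, 9, 9, 9, 9, 2]
        starts = np.arange(0, 9 * 36, 36)
        peak, strength = define_peak(starts, [25] * 9, ratios, k=6)
        assert strength == pytest.approx(9.0)
        assert (peak.start, peak.end) == (2 * 36, 7 * 36 + 25)

    def test_tie_broken_leftmost(self):
        ratios = [5, 5, 5, 5, 5, 5, 1, 5, 5, 5, 5, 5, 5]
        starts = np.arange(0, 13 * 36, 36)
        peak, _ = define_peak(starts, [25] * 13, ratios, k=6)
        assert peak.start == 0

    def test_peak_beats_every_other_window_exhaustively(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            n = int(rng.integers(6, 20))
            ratios = rng.lognormal(0, 1, n)
            starts = np.arange(0, n * 36, 36)
            _, strength = define_peak(starts, [25] * n, ratios, k=6)
            best = max(np.mean(ratios[i : i + 6]) for i in range(n - 5))
            assert strength == pytest.approx(best)


class TestRankByStrength:
    def _region(self, start, strength, chrom="c"):
        iv = GenomicInterval(chrom, start, start + 400)
        return BoundRegion(iv, iv, strength, 6)

    def test_descending_order(self):
        regions = [self._region(0, 2), self._region(500, 5), self._region(1000, 3)]
        assert [r.strength for r in rank_by_strength(regions)] == [5, 3, 2]

    def test_ties_keep_genomic_order(self):
        regions = [self._region(1000, 5), self._region(0, 5), self._region(500, 5)]
        assert [r.span.start for r in rank_by_strength(regions)] == [0, 500, 1000]

    def test_agrees_with_independent_sort_oracle(self):
        rng = np.random.default_rng(10)
        regions = [
            self._region(int(s), float(st))
            for s, st in zip(
                rng.choice(np.arange(0, 100_000, 500), 100, replace=False),
                rng.integers(1, 10, 100),  # integer strengths force ties
            )
        ]
        got = rank_by_strength(regions)
        want = sorted(
            sorted(regions, key=lambda r: r.span.start), key=lambda r: -r.strength
        )
        assert got == want
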