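"""Detector behaviour: baselines, region calls vs a brute-force scan
oracle, classification accuracy against planted truth, and monotonicity."""

import numpy as np
import pytest

from oracles import exhaustive_region_scan
from tebusco.core import (
    BaselineError,
    BuscoRecord,
    CoverageTrack,
    GenomicInterval,
)
from tebusco.coverage_busco import (
    LowCoverageWarning,
    ProfileParams,
    classify_te_associated,
    coverage_baseline,
    detect_high_coverage_regions,
)
from tebusco.experiments import score_detector


def _track(depths):
    return CoverageTrack({"c1": np.asarray(depths, dtype=np.int64)})


def _busco(start, end, bid="b1"):
    return BuscoRecord(bid, "Complete", GenomicInterval("c1", start, end))


class TestBaseline:
    def test_uniform_depth_gives_that_depth_in_both_modes(self):
        track = _track([20] * 1000)
        buscos = [_busco(100, 300)]
        for mode in ("busco_median", "genome_median"):
            p = ProfileParams(baseline_mode=mode)
            assert coverage_baseline(track, buscos, p) == 20.0

    def test_busco_median_ignores_repeat_depth_outside_genes(self):
        depths = np.full(1000, 40)
        depths[100:300] = 10  # the gene span
        p = ProfileParams(baseline_mode="busco_median")
        assert coverage_baseline(_track(depths), [_busco(100, 300)], p) == 10.0

    def test_poisson_track_baseline_near_rate(self, rng):
        depths = rng.poisson(20.0, 100_000)
        baseline = coverage_baseline(
            _track(depths), [_busco(0, 100_000)], ProfileParams()
        )
        assert 18.0 <= baseline <= 22.0

    def test_no_complete_buscos_raises(self):
        with pytest.raises(BaselineError):
            coverage_baseline(_track([5] * 10), [], ProfileParams())

    def test_low_coverage_warns(self):
        with pytest.warns(LowCoverageWarning):
            coverage_baseline(
                _track([2] * 100), [_busco(0, 100)], ProfileParams()
            )


class TestDetectRegions:
    def test_flat_depth_at_baseline_yields_nothing(self):
        regions = detect_high_coverage_regions(
            _busco(0, 1000), _track([10] * 1000), 10.0, ProfileParams()
        )
        assert regions == []

    def test_whole_span_at_3x_is_one_region_with_fold_3(self):
        regions = detect_high_coverage_regions(
            _busco(0, 1000), _track([30] * 1000), 10.0, ProfileParams()
        )
        assert len(regions) == 1
        r = regions[0]
        assert (r.interval.start, r.interval.end) == (0, 1000)
        assert r.mean_fold == pytest.approx(3.0)

    def test_planted_segment_recovered_with_high_reciprocal_overlap(
        self, rng
    ):
        depths = rng.poisson(10.0, 1500)
        depths[600:800] = rng.poisson(100.0, 200)
        regions = detect_high_coverage_regions(
            _busco(0, 1500), _track(depths), 10.0, ProfileParams()
        )
        assert len(regions) == 1
        s, e = regions[0].interval.start, regions[0].interval.end
        overlap = min(e, 800) - max(s, 600)
        assert overlap / (e - s) >= 0.9
        assert overlap / 200 >= 0.9

    @pytest.mark.parametrize("seed", range(5))
    def test_region_calls_match_exhaustive_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        depths = rng.poisson(10.0, 2000)
        n_spikes = rng.integers(0, 3)
        for _ in range(n_spikes):
            s = rng.integers(0, 1800)
            ln = rng.integers(30, 300)
            depths[s : s + ln] = rng.poisson(60.0, min(ln, 2000 - s))
        p = ProfileParams()
        got = detect_high_coverage_regions(
            _busco(0, 2000), _track(depths), 10.0, p
        )
        expected = exhaustive_region_scan(
            depths.astype(float), 10.0, p.fold_threshold,
            p.min_region_length, p.smoothing_window,
        )
        assert [(r.interval.start, r.interval.end) for r in got] == expected

    def test_reported_regions_not_within_smoothing_window(self, rng):
        depths = rng.poisson(10.0, 3000)
        for s in (500, 1000, 1600, 2400):
            depths[s : s + 120] = 200
        p = ProfileParams()
        regions = detect_high_coverage_regions(
            _busco(0, 3000), _track(depths), 10.0, p
        )
        spans = sorted(
            (r.interval.start, r.interval.end) for r in regions
        )
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert s2 - e1 >= p.smoothing_window


class TestClassify:
    def test_no_signal_means_fraction_zero(self):
        track = _track([10] * 5000)
        buscos = [_busco(i * 500, i * 500 + 400, f"b{i}") for i in range(10)]
        report = classify_te_associated(buscos, track)
        assert report.n_te_associated == 0
        assert report.fraction == 0.0

    def test_benchmark_recall_and_fpr(self, benchmark_dataset):
        _, _, buscos, _, truth, track = benchmark_dataset
        report = classify_te_associated(buscos, track)
        score = score_detector(report, truth)
        assert score.recall >= 0.9
        assert score.fpr <= 0.05

    def test_determinism(self, benchmark_dataset):
        _, _, buscos, _, _, track = benchmark_dataset
        a = classify_te_associated(buscos, track)
        b = classify_te_associated(buscos, track)
        assert a.flagged_ids() == b.flagged_ids()
        assert a.baseline == b.baseline

    def test_monotonic_in_threshold_and_length(self, benchmark_dataset):
        _, _, buscos, _, _, track = benchmark_dataset
        flagged = {}
        for t in (1.5, 2.0, 3.0, 6.0):
            p = ProfileParams(fold_threshold=t)
            flagged[t] = set(classify_te_associated(buscos, track, p).flagged_ids())
        assert flagged[6.0] <= flagged[3.0] <= flagged[2.0] <= flagged[1.5]
        by_len = {}
        for L in (25, 50, 200, 800):
            p = ProfileParams(min_region_length=L)
            by_len[L] = set(classify_te_associated(buscos, track, p).flagged_ids())
        assert by_len[800] <= by_len[200] <= by_len[50] <= by_len[25]

    def test_duplicated_counted_once_per_id(self):
        depths = np.full(4000, 10)
        depths[100:400] = 100
        depths[1100:1400] = 100
        track = _track(depths)
        buscos = [
            BuscoRecord("dup", "Duplicated", GenomicInterval("c1", 0, 500)),
            BuscoRecord("dup", "Duplicated", GenomicInterval("c1", 1000, 1500)),
            BuscoRecord("ok", "Complete", GenomicInterval("c1", 2000, 3000)),
        ]
        report = classify_te_associated(
            buscos, track, denominator_mode="complete_plus_duplicated"
        )
        assert report.n_denominator == 2
        assert report.n_te_associated == 1
        assert len(report.regions_of("dup")) == 2
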