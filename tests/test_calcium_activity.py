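import numpy as np
import pytest

from organoid_quant.calcium_activity import (
    CellActivity,
    DffTrace,
    RoiSet,
    TransientEvent,
    activity_map,
    apply_roi_edits,
    classify_cells,
    detect_cells,
    detect_transients,
    extract_and_normalize,
    fit_transient,
    kernel_peak_factor,
    network_metrics,
)
from organoid_quant.core_io import Image2D, Movie, ValidationError

from conftest import make_trace_from_kernel


class TestActivityMap:
    def test_static_movie_gives_zero_map(self):
        movie = Movie(np.full((10, 16, 16), 0.5))
        amap = activity_map(movie, 0.1)
        np.testing.assert_allclose(amap.pixels, 0.0, atol=1e-12)

    def test_blinking_pixel_is_map_maximum_without_filtering(self):
        frames = np.full((20, 16, 16), 0.2)
        frames[::2, 5, 9] = 0.8
        amap = activity_map(Movie(frames), lowpass_cutoff=None)
        assert np.unravel_index(np.argmax(amap.pixels), (16, 16)) == (5, 9)

    def test_blinking_spots_found_at_true_centers(self, rng):
        centers = [(8, 8), (8, 40), (40, 8), (40, 40), (24, 24)]
        yy, xx = np.mgrid[:48, :48]
        frames = np.full((200, 48, 48), 0.2)
        for cy, cx in centers:
            prof = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / 8.0)
            onoff = (rng.random(200) < 0.3).astype(float)
            frames += 0.2 * onoff[:, None, None] * prof
        frames += rng.normal(0, 0.04, frames.shape)  # SNR 5 on the blink amplitude
        amap = activity_map(Movie(np.clip(frames, 0, None)), 0.1)
        rois = detect_cells(amap, min_separation_px=6, n_max=5)
        assert len(rois) == 5
        for cy, cx in centers:
            assert min((cy - y) ** 2 + (cx - x) ** 2 for y, x in rois.centers) <= 4

    def test_single_frame_rejected(self):
        with pytest.raises(ValidationError):
            Movie(np.zeros((1, 8, 8)))


class TestDetectCells:
    def test_close_peaks_keep_only_higher(self):
        arr = np.zeros((32, 32))
        arr[10, 10] = 1.0
        arr[10, 13] = 0.8  # 3 px away
        rois = detect_cells(Image2D(arr), min_separation_px=5)
        assert rois.centers == [(10, 10)]

    def test_flat_map_gives_no_rois(self):
        rois = detect_cells(Image2D(np.full((32, 32), 0.5)))
        assert len(rois) == 0

    def test_edits_add_and_remove(self):
        rois = RoiSet(centers=[(5, 5), (20, 20)], radius_px=4)
        edited = apply_roi_edits(rois, {"remove": [0], "add": [[10, 12]]}, (32, 32))
        assert (5, 5) not in edited.centers
        assert (10, 12) in edited.centers

    def test_edit_outside_frame_rejected(self):
        rois = RoiSet(centers=[], radius_px=4)
        with pytest.raises(ValidationError):
            apply_roi_edits(rois, {"add": [[100, 1]]}, (32, 32))


class TestExtractNormalize:
    def _movie_with_trace(self, cell_values):
        frames = np.tile(np.asarray(cell_values)[:, None, None], (1, 21, 21))
        return Movie(frames), RoiSet(centers=[(10, 10)], radius_px=3)

    def test_constant_trace_is_zero(self):
        movie, rois = self._movie_with_trace(np.full(200, 0.5))
        (trace,) = extract_and_normalize(movie, rois)
        np.testing.assert_allclose(trace.values, 0.0, atol=1e-12)

    def test_step_plateau_recovers_relative_change(self):
        values = np.full(400, 0.50)
        values[200:] = 0.55  # +10%
        movie, rois = self._movie_with_trace(values)
        (trace,) = extract_and_normalize(movie, rois)
        assert trace.values[210:220].mean() == pytest.approx(0.10, abs=0.005)

    def test_zero_baseline_flags_trace_invalid(self):
        movie, rois = self._movie_with_trace(np.zeros(100))
        (trace,) = extract_and_normalize(movie, rois)
        assert not trace.valid

    def test_amplitude_recovered_under_slow_drift(self):
        rate = 4.0
        t = np.arange(1200) / rate
        base = 0.5 * (1.0 - 0.1 * t / 300.0)  # 10% linear bleed
        dff = np.zeros_like(t)
        for t0 in (60.0, 150.0, 240.0):
            dt = np.clip(t - t0, 0, None)
            dff += 0.2 / kernel_peak_factor(0.5, 2.0) * (1 - np.exp(-dt / 0.5)) * np.exp(-dt / 2.0)
        movie, rois = self._movie_with_trace(base * (1 + dff))
        (trace,) = extract_and_normalize(movie, rois)
        events = detect_transients(trace)
        assert len(events) == 3
        for e in events:
            assert e.amplitude == pytest.approx(0.2, rel=0.10)


class TestDetectTransients:
    def test_flat_trace_gives_no_events(self):
        trace = DffTrace(np.zeros(100), np.ones(100), 4.0, 3)
        assert detect_transients(trace) == []

    def test_single_kernel_above_threshold_detected(self):
        trace = make_trace_from_kernel(amp=0.05)
        events = detect_transients(trace)
        assert len(events) == 1
        assert events[0].amplitude == pytest.approx(0.05, rel=0.15)

    def test_kernel_below_two_percent_rejected(self):
        trace = make_trace_from_kernel(amp=0.01)
        assert detect_transients(trace) == []

    def test_event_count_non_increasing_in_threshold(self):
        rng = np.random.default_rng(3)
        v = np.zeros(1200)
        t = np.arange(1200) / 4.0
        for t0 in rng.uniform(10, 280, 8):
            dt = np.clip(t - t0, 0, None)
            amp = rng.uniform(0.02, 0.3)
            v += amp / kernel_peak_factor(0.5, 2.0) * (1 - np.exp(-dt / 0.5)) * np.exp(-dt / 2.0)
        v += rng.normal(0, 0.003, 1200)
        from scipy import ndimage as ndi

        trace = DffTrace(ndi.uniform_filter1d(v, 3), np.ones(1200), 4.0, 3, raw_values=v)
        counts = [
            len(detect_transients(trace, amplitude_threshold=th))
            for th in (0.01, 0.02, 0.05, 0.1, 0.2)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_onset_before_peak_before_offset(self):
        trace = make_trace_from_kernel(amp=0.1)
        (e,) = detect_transients(trace)
        assert e.onset_idx < e.peak_idx <= e.offset_idx


class TestFitTransient:
    @pytest.mark.parametrize("tau_r,tau_d", [(0.5, 2.0), (1.0, 3.0)])
    def test_noiseless_kernel_recovered_within_5_percent(self, tau_r, tau_d):
        trace = make_trace_from_kernel(tau_r=tau_r, tau_d=tau_d, amp=0.05)
        (e,) = detect_transients(trace)
        fitted = fit_transient(trace, e)
        assert fitted.fit_ok
        assert fitted.rise_time_s == pytest.approx(tau_r, rel=0.05)
        assert fitted.decay_time_s == pytest.approx(tau_d, rel=0.05)
        assert fitted.amplitude == pytest.approx(0.05, rel=0.05)

    def test_slow_rise_classified_above_tau_star(self):
        trace = make_trace_from_kernel(tau_r=3.0, tau_d=4.0, amp=0.1, duration_s=60.0)
        (e,) = detect_transients(trace)
        fitted = fit_transient(trace, e)
        assert fitted.fit_ok and fitted.rise_time_s > 1.5

    def test_degenerate_two_point_rise_falls_back_to_raw_peak(self):
        trace = make_trace_from_kernel(amp=0.05)
        e = TransientEvent(onset_idx=40, peak_idx=41, offset_idx=60, amplitude=0.05)
        fitted = fit_transient(trace, e)
        assert not fitted.fit_ok
        assert fitted.amplitude == 0.05


class TestClassify:
    def _cell(self, rises):
        events = [
            TransientEvent(0, 2, 5, 0.1, rise_time_s=r, decay_time_s=2.0, fit_ok=True)
            for r in rises
        ]
        return CellActivity(roi_id=0, events=events)

    @pytest.mark.parametrize(
        "rises,expected",
        [([1.0, 1.1, 0.9], "fast"), ([2.0, 2.2], "slow"), ([1.5, 1.5], "slow")],
    )
    def test_median_rise_against_tau_star(self, rises, expected):
        (cell,) = classify_cells([self._cell(rises)])
        assert cell.cell_class == expected

    def test_cell_without_fitted_events_is_slow(self):
        (cell,) = classify_cells([CellActivity(roi_id=0)])
        assert cell.cell_class == "slow"

    def test_monotone_increasing_rises_never_unlocks_fast(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            rises = list(rng.uniform(0.3, 3.0, 5))
            (before,) = classify_cells([self._cell(rises)])
            (after,) = classify_cells([self._cell([r + rng.uniform(0, 2) for r in rises])])
            if before.cell_class == "slow":
                assert after.cell_class == "slow"


class TestNetworkMetrics:
    def _cells(self, peak_times_s, rate=4.0):
        cells = []
        for i, times in enumerate(peak_times_s):
            events = [
                TransientEvent(
                    int(t * rate) - 2, int(t * rate), int(t * rate) + 8, 0.1,
                    rise_time_s=0.5, decay_time_s=2.0, fit_ok=True,
                )
                for t in times
            ]
            cells.append(CellActivity(roi_id=i, events=events, cell_class="fast"))
        return cells

    def test_all_cells_in_one_bin_gives_synchrony_one(self):
        cells = self._cells([[100.2]] * 10)
        m = network_metrics(cells, 300.0)
        assert m.synchrony == 1.0
        assert m.active_fraction == 1.0

    def test_events_in_distinct_bins_give_one_over_n(self):
        cells = self._cells([[10.0 * (i + 1)] for i in range(10)])
        m = network_metrics(cells, 300.0)
        assert m.synchrony == pytest.approx(0.1)

    def test_zero_active_cells_warns_and_zeroes(self):
        cells = [CellActivity(roi_id=0, cell_class="slow")]
        with pytest.warns(UserWarning):
            m = network_metrics(cells, 300.0)
        assert m.synchrony == 0.0 and m.mean_frequency_per_min == 0.0

    def test_slow_cells_excluded_from_rates_but_counted_in_total(self):
        cells = self._cells([[50.0], [100.0]])
        cells.append(CellActivity(roi_id=9, cell_class="slow",
                                  events=[TransientEvent(0, 4, 10, 0.5)]))
        m = network_metrics(cells, 300.0)
        assert m.n_cells_total == 3
        assert m.n_active_fast == 2
        assert m.active_fraction == pytest.approx(2 / 3)

    def test_poisson_synchrony_matches_monte_carlo_oracle(self):
        """Mean peak-coincidence synchrony of independent Poisson trains agrees
        with a direct Monte-Carlo evaluation of the same definition."""
        rng = np.random.default_rng(42)
        duration, rate_per_min, n_cells, bin_s = 300.0, 1.0, 20, 1.0
        n_bins = int(duration / bin_s)

        def oracle_once(r):
            counts = np.zeros(n_bins)
            active = 0
            for _ in range(n_cells):
                n = r.poisson(rate_per_min * duration / 60)
                if n == 0:
                    continue
                active += 1
                bins = np.unique((r.uniform(0, duration, n) // bin_s).astype(int))
                counts[bins] += 1
            return counts.max() / active if active else 0.0

        oracle = np.mean([oracle_once(rng) for _ in range(3000)])

        vals = []
        for seed in range(100):
            r = np.random.default_rng(1000 + seed)
            cells = []
            for i in range(n_cells):
                times = r.uniform(0, duration, r.poisson(rate_per_min * duration / 60))
                cells.append(
                    CellActivity(
                        roi_id=i,
                        cell_class="fast",
                        events=[
                            TransientEvent(int(t * 4) - 1, int(t * 4), int(t * 4) + 4, 0.1)
                            for t in times
                        ],
                    )
                )
            vals.append(network_metrics(cells, duration, bin_s, 4.0).synchrony)
        assert np.mean(vals) == pytest.approx(oracle, abs=0.05)


class TestPipelineInvariants:
    def test_scaling_movie_intensity_leaves_events_unchanged(self):
        from organoid_quant.synthetic import gen_calcium_movie

        movie, _ = gen_calcium_movie(
            n_cells=5, rate_per_min=2.0, duration_s=80.0, shape=(64, 64), snr=8.0, seed=4
        )
        from organoid_quant.calcium_activity import analyze_movie

        _, _, cells1, _ = analyze_movie(movie)
        scaled = Movie(movie.frames * 3.7, frame_rate_hz=movie.frame_rate_hz)
        _, _, cells2, _ = analyze_movie(scaled)
        ev1 = [(e.onset_idx, e.peak_idx, round(e.amplitude, 9)) for c in cells1 for e in c.events]
        ev2 = [(e.onset_idx, e.peak_idx, round(e.amplitude, 9)) for c in cells2 for e in c.events]
        assert ev1 == ev2

    def test_pipeline_is_deterministic(self):
        from organoid_quant.synthetic import gen_calcium_movie
        from organoid_quant.calcium_activity import analyze_movie

        movie, _ = gen_calcium_movie(
            n_cells=5, rate_per_min=2.0, duration_s=80.0, shape=(64, 64), snr=8.0, seed=4
        )
        _, _, cells1, m1 = analyze_movie(movie)
        _, _, cells2, m2 = analyze_movie(movie)
        assert m1 == m2
        for c1, c2 in zip(cells1, cells2):
            assert [(e.onset_idx, e.amplitude) for e in c1.events] == [
                (e.onset_idx, e.amplitude) for e in c2.events
            ]
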