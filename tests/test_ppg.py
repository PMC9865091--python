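import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from socksig.io import SignalRecord
from socksig.ppg import (
    BandPassSpec,
    DetectionCounts,
    HRSeries,
    accuracy_from_ppv_sensitivity,
    detect_systolic_peaks,
    filter_ppg,
    grid_search_cutoffs,
    hr_error,
    instantaneous_hr,
    make_grid,
    score_detections,
)
from socksig.simulate import PpgSimConfig, simulate_ppg
from conftest import brute_force_match


def clean_ppg(mean_hr=60, duration=60.0, fs=100.0, seed=3):
    cfg = PpgSimConfig(
        duration=duration, sampling_rate=fs, mean_hr=mean_hr, hr_sd=0.0,
        noise_sd=0.0, baseline_wander_amp=0.0, seed=seed,
    )
    return simulate_ppg(cfg)


class TestBandPassSpec:
    def test_order_of_cutoffs_enforced(self):
        with pytest.raises(ValueError):
            BandPassSpec(fcl=8.0, fch=1.0)

    def test_cutoff_above_nyquist_rejected_at_filter(self):
        rec = SignalRecord(np.random.default_rng(0).random(1000), 20.0)
        with pytest.raises(ValueError, match="Nyquist"):
            filter_ppg(rec, BandPassSpec(fcl=1.0, fch=15.0))


class TestFilterPpg:
    def test_dc_removed(self):
        rec = SignalRecord(np.full(3000, 7.0), 100.0)
        assert np.abs(filter_ppg(rec).samples).max() < 1e-6

    @pytest.mark.parametrize(
        "freq,min_gain,max_gain",
        [(1.2, 10 ** (-3 / 20), 1.05), (0.1, 0.0, 0.1)],
    )
    def test_band_edges(self, freq, min_gain, max_gain):
        fs = 100.0
        t = np.arange(0, 60, 1 / fs)
        rec = SignalRecord(np.sin(2 * np.pi * freq * t), fs)
        y = filter_ppg(rec).samples[int(20 * fs): int(40 * fs)]
        gain = (y.max() - y.min()) / 2
        assert min_gain <= gain <= max_gain


class TestDetectSystolicPeaks:
    def test_clean_rhythm_detected_within_tolerance(self):
        rec, truth = clean_ppg()
        peaks = detect_systolic_peaks(filter_ppg(rec))
        counts = score_detections(truth.beat_times, peaks, tolerance=0.05)
        assert counts.sensitivity == 1.0 and counts.ppv == 1.0

    def test_flat_signal_no_peaks(self):
        assert detect_systolic_peaks(SignalRecord(np.zeros(1000), 100.0)).size == 0

    def test_amplitude_scale_invariance(self):
        rec, _ = clean_ppg()
        filt = filter_ppg(rec)
        p1 = detect_systolic_peaks(filt)
        p2 = detect_systolic_peaks(filt.copy_with(samples=filt.samples * 10))
        np.testing.assert_array_equal(p1, p2)


class TestScoreDetections:
    def test_perfect_detection(self):
        t = np.arange(10.0)
        c = score_detections(t, t, 0.1)
        assert c.accuracy == c.ppv == c.sensitivity == 1.0

    def test_small_example_counts(self):
        c = score_detections([1.0, 2.0, 3.0], [1.0, 2.5], tolerance=0.1)
        assert (c.tp, c.fp, c.fn) == (1, 1, 2)
        assert c.accuracy == pytest.approx(0.25)

    def test_agrees_with_brute_force(self, rng):
        for _ in range(200):
            truth = np.sort(rng.uniform(0, 10, int(rng.integers(0, 7))))
            det = np.sort(rng.uniform(0, 10, int(rng.integers(0, 7))))
            c = score_detections(truth, det, tolerance=0.5)
            n_opt, _ = brute_force_match(truth, det, 0.5)
            assert c.tp == n_opt

    @settings(derandomize=True, max_examples=100)
    @given(
        tp=st.integers(1, 1000), fp=st.integers(0, 1000), fn=st.integers(0, 1000)
    )
    def test_metric_identity(self, tp, fp, fn):
        """1/accuracy = 1/ppv + 1/sensitivity - 1 whenever tp > 0."""
        c = DetectionCounts(tp=tp, fp=fp, fn=fn)
        assert 1 / c.accuracy == pytest.approx(1 / c.ppv + 1 / c.sensitivity - 1)

    def test_implied_accuracy_helper(self):
        assert accuracy_from_ppv_sensitivity(0.9069, 0.9656) == pytest.approx(
            0.8785, abs=5e-5
        )

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            score_detections([1.0], [1.0], tolerance=-0.1)


class TestGridSearch:
    def test_published_style_grids_contain_selected_cutoffs(self):
        fcl = make_grid(0.5, 1.2, 10)
        fch = make_grid(8.9, 25.0, 30)
        assert 0.97 in np.round(fcl, 2)
        assert 11.12 in np.round(fch, 2)

    def test_noiseless_plateau_contains_default_band(self):
        rec, truth = clean_ppg(duration=30.0)
        res = grid_search_cutoffs(
            rec, truth.beat_times, make_grid(0.5, 1.5, 3), make_grid(6, 12, 4)
        )
        assert res.best_accuracy == 1.0
        i = list(np.round(res.fcl_grid, 2)).index(1.0)
        j = list(res.fch_grid).index(8.0)
        assert res.accuracy_surface[i, j] == 1.0

    def test_refined_grid_never_worse(self):
        rec, truth = clean_ppg(duration=20.0, mean_hr=72, seed=9)
        coarse_fcl, coarse_fch = make_grid(0.5, 1.5, 2), make_grid(6, 10, 2)
        fine_fcl = np.unique(np.concatenate([coarse_fcl, [1.0]]))
        fine_fch = np.unique(np.concatenate([coarse_fch, [8.0]]))
        a = grid_search_cutoffs(rec, truth.beat_times, coarse_fcl, coarse_fch)
        b = grid_search_cutoffs(rec, truth.beat_times, fine_fcl, fine_fch)
        assert b.best_accuracy >= a.best_accuracy

    def test_tie_break_prefers_low_fch_then_low_fcl(self):
        rec, truth = clean_ppg(duration=20.0)
        res = grid_search_cutoffs(
            rec, truth.beat_times, make_grid(0.8, 1.2, 2), make_grid(7, 9, 2)
        )
        surf = res.accuracy_surface
        js = np.argwhere(surf == res.best_accuracy)
        j_min = min(j for _, j in js)
        i_min = min(i for i, j in js if j == j_min)
        assert res.best_spec.fch == res.fch_grid[j_min]
        assert res.best_spec.fcl == res.fcl_grid[i_min]

    def test_empty_labels_rejected(self):
        rec, _ = clean_ppg(duration=15.0)
        with pytest.raises(ValueError):
            grid_search_cutoffs(rec, [], make_grid(0.5, 1, 2), make_grid(6, 8, 2))


class TestInstantaneousHr:
    def test_uniform_rhythm(self):
        hr = instantaneous_hr([0.0, 1.0, 2.0, 3.0])
        np.testing.assert_allclose(hr.times, [1.0, 2.0, 3.0])
        np.testing.assert_allclose(hr.hr, 60.0)

    def test_half_second_interval(self):
        hr = instantaneous_hr([0.0, 0.5])
        assert hr.hr[0] == pytest.approx(120.0)

    def test_alternating_intervals(self):
        hr = instantaneous_hr([0.0, 0.5, 1.5, 2.0, 3.0])
        np.testing.assert_allclose(hr.hr, [120.0, 60.0, 120.0, 60.0])

    def test_single_peak_rejected(self):
        with pytest.raises(ValueError):
            instantaneous_hr([1.0])


class TestHrError:
    def test_identical_series_zero_error(self):
        hr = instantaneous_hr(np.arange(0, 30.0))
        bias, sd, rmse = hr_error(hr, hr)
        assert bias == 0.0 and rmse == 0.0

    def test_constant_offset(self):
        t = np.arange(0, 30.0)
        true = HRSeries(times=t, hr=np.full(t.size, 60.0))
        pred = HRSeries(times=t, hr=np.full(t.size, 65.0))
        bias, sd, rmse = hr_error(true, pred)
        assert bias == pytest.approx(-5.0)
        assert rmse == pytest.approx(5.0)

    def test_doubled_beat_overestimates_hr(self):
        """An extra detected peak splits one interval: negative bias."""
        truth = np.arange(0, 30.0)
        doubled = np.sort(np.append(truth, 15.5))
        bias, _, rmse = hr_error(
            instantaneous_hr(truth), instantaneous_hr(doubled)
        )
        assert rmse > 0
        assert bias < 0

    def test_disjoint_series_rejected(self):
        a = instantaneous_hr([0.0, 1.0, 2.0])
        b = instantaneous_hr([10.0, 11.0, 12.0])
        with pytest.raises(ValueError):
            hr_error(a, b)


class TestEndToEnd:
    def test_hr_recovery_across_rates_and_noise(self):
        """50-120 BPM with noise: sensitivity > 0.95 and RMSE < 2 BPM for
        >=90% of seeds, using a band that covers the lowest fundamental."""
        spec = BandPassSpec(fcl=0.5, fch=8.0)
        ok = 0
        n_seeds = 50
        for s in range(n_seeds):
            hr = 50 + (s % 8) * 10
            cfg = PpgSimConfig(
                duration=60, sampling_rate=500, mean_hr=hr, hr_sd=2.0,
                noise_sd=0.05, seed=1000 + s,
            )
            rec, truth = simulate_ppg(cfg)
            peaks = detect_systolic_peaks(filter_ppg(rec, spec))
            if peaks.size < 2:
                continue
            counts = score_detections(truth.beat_times, peaks, tolerance=0.1)
            rmse = hr_error(
                instantaneous_hr(truth.beat_times), instantaneous_hr(peaks)
            )[2]
            ok += counts.sensitivity > 0.95 and rmse < 2.0
        assert ok / n_seeds >= 0.9
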