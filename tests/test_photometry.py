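"""Isosbestic correction, epoch z-scoring, peak detection and alignment."""
import math
from dataclasses import replace

import numpy as np
import pytest

from loomphot import photometry as ph
from loomphot.simulate import (PhotometrySimParams, simulate_photometry,
                               transient_kernel)
from loomphot.stimulus import LoomParams, loom_schedule


def make_trace(x, fs=100.0, as_z=False):
    t = np.arange(len(x)) / fs
    tr = ph.CorrectedTrace(time=t, dff=np.asarray(x, float), fit_slope=1.0,
                           fit_intercept=0.0, sampling_rate=fs)
    if as_z:
        tr.z = tr.dff.copy()
    return tr


def make_recording(f465, f405, fs=100.0):
    t = np.arange(len(f465)) / fs
    return ph.PhotometryRecording(time=t, f465=np.asarray(f465, float),
                                  f405=np.asarray(f405, float),
                                  sampling_rate=fs)


def grid_refine_ols(x, y, tol=1e-10):
    """Brute-force least squares by iterative grid refinement.

    Works in centered coordinates, where the slope decouples from the
    intercept: SSE(s) = sum((y - ybar) - s (x - xbar))^2 is refined on a 1-D
    grid and the intercept follows as ybar - s xbar.
    """
    xc, yc = x - x.mean(), y - y.mean()
    s0, span = 0.0, 10.0
    for _ in range(80):
        ss = np.linspace(s0 - span, s0 + span, 41)
        sse = ((yc[None, :] - ss[:, None] * xc[None, :]) ** 2).sum(axis=1)
        s0 = float(ss[int(np.argmin(sse))])
        span *= 0.2
        if span < tol:
            break
    return s0, float(y.mean() - s0 * x.mean())


def naive_prominent_peaks(x, min_prominence):
    """Independent local-maximum + prominence scan (no scipy)."""
    out = []
    n = len(x)
    for i in range(1, n - 1):
        if not (x[i - 1] < x[i] and x[i] >= x[i + 1]):
            continue
        lmin = x[i]
        j = i - 1
        while j >= 0 and x[j] <= x[i]:
            lmin = min(lmin, x[j])
            j -= 1
        rmin = x[i]
        j = i + 1
        while j < n and x[j] <= x[i]:
            rmin = min(rmin, x[j])
            j += 1
        if x[i] - max(lmin, rmin) >= min_prominence:
            out.append((i, x[i]))
    return out


class TestIsosbesticCorrect:
    def test_exact_linear_relation(self, rng):
        f405 = 50 + rng.standard_normal(200)
        rec = make_recording(2 * f405 + 1, f405)
        tr = ph.isosbestic_correct(rec)
        assert tr.fit_slope == pytest.approx(2.0, abs=1e-9)
        assert tr.fit_intercept == pytest.approx(1.0, abs=1e-7)
        assert np.allclose(tr.dff, 0.0, atol=1e-8)
        # stored coefficients reproduce dff exactly
        assert np.allclose(tr.dff,
                           rec.f465 - (tr.fit_slope * rec.f405 + tr.fit_intercept))

    def test_constant_reference_rejected(self):
        rec = make_recording(np.arange(50.0), np.full(50, 3.0))
        with pytest.raises(ph.DegenerateFitError):
            ph.isosbestic_correct(rec)

    def test_nan_sample_reported_with_index(self, rng):
        f405 = 50 + rng.standard_normal(50)
        f465 = f405.copy()
        f465[17] = np.nan
        with pytest.raises(ph.PhotometryError, match="index 17"):
            ph.isosbestic_correct(make_recording(f465, f405))

    def test_matches_grid_refinement_oracle_and_reduces_artifact(self):
        params = PhotometrySimParams(duration=30.0, artifact_sd=1.0,
                                     white_noise_sd=0.2, spontaneous_rate=0.0,
                                     seed=5)
        rec, gt = simulate_photometry(params)
        tr = ph.isosbestic_correct(rec)
        s, c = grid_refine_ols(rec.f405, rec.f465)
        assert tr.fit_slope == pytest.approx(s, abs=1e-6)
        assert tr.fit_intercept == pytest.approx(c, abs=1e-4)
        bleach = (params.bleach_amplitude_465
                  * np.exp(-rec.time / params.bleach_tau_465))
        detrended = rec.f465 - bleach - params.baseline_465
        assert tr.dff.var() <= 0.1 * detrended.var()

    def test_correction_is_idempotent(self, rng):
        f405 = 50 + np.sin(np.arange(200) / 10.0)
        rec = make_recording(3 * f405 + 2, f405)
        tr = ph.isosbestic_correct(rec)
        second = ph.isosbestic_correct(make_recording(tr.dff, f405))
        assert abs(second.fit_slope) < 1e-6


class TestZScore:
    def test_three_sample_window(self):
        tr = make_trace([1.0, 2.0, 3.0], fs=1.0)
        z = ph.zscore_epoch(tr, (0.0, 2.0))
        assert np.allclose(z.z, [-1.0, 0.0, 1.0])

    def test_whole_trace_normalization_identity(self, rng):
        tr = make_trace(rng.standard_normal(500) * 3 + 7)
        z = ph.zscore_epoch(tr, (tr.time[0], tr.time[-1]))
        assert z.z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(300)
        z1 = ph.zscore_epoch(make_trace(x), (0.5, 2.5)).z
        z2 = ph.zscore_epoch(make_trace(4.2 * x + 11.0), (0.5, 2.5)).z
        assert np.allclose(z1, z2, atol=1e-9)

    def test_disjoint_windows_match_direct_recomputation(self, rng):
        x = rng.standard_normal(1000)
        tr = make_trace(x)
        for window in [(0.0, 3.0), (6.0, 9.99)]:
            z = ph.zscore_epoch(tr, window)
            mask = (tr.time >= window[0]) & (tr.time <= window[1])
            mu, sd = x[mask].mean(), x[mask].std(ddof=1)
            assert np.allclose(z.z, (x - mu) / sd, atol=1e-12)
        za = ph.zscore_epoch(tr, (0.0, 3.0)).z
        zb = ph.zscore_epoch(tr, (6.0, 9.99)).z
        assert not np.allclose(za, zb)

    def test_constant_window_rejected(self):
        tr = make_trace(np.r_[np.zeros(100), np.arange(100.0)])
        with pytest.raises(ph.PhotometryError):
            ph.zscore_epoch(tr, (0.0, 0.5))


class TestDetectPeaks:
    def test_single_triangular_pulse(self):
        x = np.zeros(1000)
        x[400:501] = np.linspace(0, 3.0, 101)
        x[500:601] = np.linspace(3.0, 0, 101)
        peaks = ph.detect_peaks(make_trace(x, as_z=True), (0.0, 9.99))
        assert len(peaks) == 1
        assert peaks[0].time == pytest.approx(5.0, abs=1e-9)
        assert peaks[0].amplitude == pytest.approx(3.0)

    def test_two_injected_kernels_recovered(self, rng):
        fs = 100.0
        t = np.arange(3000) / fs
        x = (2.0 * transient_kernel(t - 10.0) + 4.0 * transient_kernel(t - 20.0)
             + 0.05 * rng.standard_normal(t.size))
        peaks = ph.detect_peaks(make_trace(x, as_z=True), (5.0, 29.99),
                                min_prominence=0.5)
        big = sorted(peaks, key=lambda p: p.amplitude)[-2:]
        big = sorted(big, key=lambda p: p.time)
        # argmax-per-window brute-force oracle for the true peak locations
        for ev, (lo, hi), amp in zip(big, [(9.0, 15.0), (19.0, 25.0)], [2.0, 4.0]):
            w = (t >= lo) & (t <= hi)
            t_true = t[w][np.argmax(x[w])]
            assert ev.time == pytest.approx(t_true, abs=0.011)  # one sample
            assert ev.amplitude == pytest.approx(amp, rel=0.1)

    def test_flat_trace_has_no_peaks(self):
        peaks = ph.detect_peaks(make_trace(np.zeros(500), as_z=True), (0.0, 4.99))
        assert peaks == []

    def test_plateau_tie_broken_to_earliest_sample(self):
        x = np.zeros(100)
        x[40:45] = 2.0
        peaks = ph.detect_peaks(make_trace(x, as_z=True), (0.0, 0.99))
        assert len(peaks) == 1
        assert peaks[0].time == pytest.approx(0.40)

    def test_empty_window_rejected(self):
        with pytest.raises(ph.PhotometryError):
            ph.detect_peaks(make_trace(np.zeros(100), as_z=True), (5.0, 6.0))


class TestBaselinePeak:
    def test_lone_peak_before_onset(self):
        fs = 100.0
        x = np.zeros(1000)
        x[558:561] = [1.0, 1.5, 1.0]  # peak at t = 5.59, onset - 0.41
        amp = ph.baseline_peak(make_trace(x, as_z=True), stimulus_onset=6.0)
        assert amp == pytest.approx(1.5)

    def test_monotone_ramp_falls_back_to_window_max(self):
        x = np.linspace(0, 2.0, 1000)
        tr = make_trace(x, as_z=True)
        ev, fallback = ph.window_response(tr, (5.0, 6.0))
        assert fallback
        amp = ph.baseline_peak(tr, stimulus_onset=6.0)
        mask = (tr.time >= 5.0) & (tr.time < 6.0)
        assert amp == pytest.approx(x[mask].max())

    def test_onset_too_early_rejected(self):
        with pytest.raises(ph.PhotometryError):
            ph.baseline_peak(make_trace(np.zeros(200), as_z=True), 0.5)

    def test_matches_brute_force_window_scan_on_noise(self, rng):
        """Over 100 noise traces, the baseline statistic equals the
        brute-force window maximum, and when the maximum coincides with a
        prominent local peak the naive prominence scan agrees on it."""
        for _ in range(100):
            x = rng.standard_normal(300)
            tr = make_trace(x, as_z=True)
            amp = ph.baseline_peak(tr, stimulus_onset=2.0, min_separation=0.01)
            sl = slice(np.searchsorted(tr.time, 1.0),
                       np.searchsorted(tr.time, 2.0))
            seg = x[sl]
            assert amp == pytest.approx(seg.max(), abs=1e-12)
            cands = naive_prominent_peaks(seg, 0.5)
            if cands and math.isclose(max(v for _, v in cands), seg.max()):
                ev, fallback = ph.window_response(tr, (1.0, 2.0),
                                                  min_separation=0.01)
                assert not fallback
                best_i = max(cands, key=lambda c: c[1])[0]
                assert ev.time == pytest.approx(tr.time[sl.start + best_i],
                                                abs=1e-9)


class TestAlignToEvents:
    def test_constant_trace_single_event(self):
        tr = make_trace(np.full(1000, 2.5), as_z=True)
        mat = ph.align_to_events(tr, [5.0], pre=1.0, post=1.0)
        assert mat.values.shape == (1, 201)
        assert np.allclose(mat.values, 2.5)
        assert np.allclose(mat.sem, 0.0)

    def test_identical_transients_have_zero_sem(self):
        fs = 100.0
        t = np.arange(11000) / fs
        x = sum(transient_kernel(t - e) for e in (10.0, 50.0, 90.0))
        mat = ph.align_to_events(make_trace(x, as_z=True), [10.0, 50.0, 90.0],
                                 pre=2.0, post=3.0)
        assert mat.n_events == 3
        assert np.allclose(mat.mean, mat.values[0], atol=1e-9)
        assert np.max(mat.sem) < 1e-9

    def test_mean_matches_column_means(self, rng):
        x = rng.standard_normal(5000)
        mat = ph.align_to_events(make_trace(x, as_z=True),
                                 [10.0, 20.0, 30.0, 40.0], pre=1.0, post=1.0)
        assert np.allclose(mat.mean, mat.values.mean(axis=0), atol=1e-12)
        n = mat.n_events
        assert np.allclose(mat.sem,
                           mat.values.std(axis=0, ddof=1) / math.sqrt(n),
                           atol=1e-12)

    def test_uncovered_events_dropped_then_error(self):
        tr = make_trace(np.zeros(500), as_z=True)
        mat = ph.align_to_events(tr, [0.1, 2.5], pre=1.0, post=1.0)
        assert mat.n_events == 1
        with pytest.raises(ph.PhotometryError):
            ph.align_to_events(tr, [0.1], pre=1.0, post=1.0)

    @pytest.mark.parametrize("n", [4, 16, 64])
    def test_noise_mean_shrinks_with_event_count(self, rng, n):
        fs = 100.0
        x = rng.standard_normal(int(fs * (n * 4 + 20)))
        events = 5.0 + 4.0 * np.arange(n)
        mat = ph.align_to_events(make_trace(x, as_z=True), events,
                                 pre=1.0, post=1.0)
        m = mat.relative_time.size
        bound = 3.0 * math.sqrt(2 * math.log(m)) / math.sqrt(n)
        assert np.max(np.abs(mat.mean)) < bound


class TestStimulusResponse:
    def test_habituation_by_construction(self):
        fs = 100.0
        t = np.arange(4000) / fs
        train = loom_schedule(LoomParams(), 20.0)
        x = 4.0 * transient_kernel(t - 20.45)  # response to disk 1 only
        events, baseline = ph.stimulus_response(make_trace(x, as_z=True), train)
        amps = [e.amplitude for e in events]
        # the disk-2 window still contains the slowly decaying disk-1 tail,
        # so the strong habituation contrast is against the later disks
        assert amps[0] > amps[1] > amps[2] > amps[3] > amps[4]
        assert amps[0] > 3 * max(amps[2:])
        assert baseline < 0.5

    def test_reference_times_equal_schedule(self, rng):
        fs = 100.0
        t = np.arange(4000) / fs
        x = rng.standard_normal(t.size)
        train = loom_schedule(LoomParams(), 20.0)
        events, _ = ph.stimulus_response(make_trace(x, as_z=True), train)
        for ev, onset in zip(events, train.disk_onsets):
            assert ev.time - ev.latency == pytest.approx(onset, abs=1e-9)
            assert ev.reference_label.startswith("disk")

    def test_train_past_trace_end_rejected(self):
        tr = make_trace(np.zeros(500), as_z=True)
        with pytest.raises(ph.PhotometryError):
            ph.stimulus_response(tr, loom_schedule(LoomParams(), 2.0))


def test_lowpass_recording_attenuates_noise_preserves_mean(rng):
    f405 = 50 + rng.standard_normal(2000)
    rec = make_recording(80 + rng.standard_normal(2000), f405)
    out = ph.lowpass_recording(rec, 2.0)
    assert out.f465.std() < 0.5 * rec.f465.std()
    assert out.f465.mean() == pytest.approx(rec.f465.mean(), abs=0.1)
    with pytest.raises(ph.PhotometryError):
        ph.lowpass_recording(rec, 60.0)
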