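"""Kinematics, trigger rule and behavioral segmentation."""
from dataclasses import replace

import numpy as np
import pytest

from loomphot import behavior as bv
from loomphot.simulate import BehaviorSimParams, PhotometrySimParams, simulate_session
from loomphot.stimulus import LoomParams, loom_schedule

GEO = bv.ArenaGeometry()


def make_track(t, x, y, geometry=None):
    return bv.TrackingTrace(time=np.asarray(t, float), x=np.asarray(x, float),
                            y=np.asarray(y, float), geometry=geometry)


class TestKinematics:
    def test_uniform_motion(self):
        t = np.arange(100) / 30.0
        kin = bv.compute_kinematics(make_track(t, 10 * t, np.full(t.size, 5.0)),
                                    smooth_window=0.0)
        assert np.allclose(kin.speed, 10.0, atol=1e-9)
        assert np.allclose(kin.acceleration[2:-2], 0.0, atol=1e-6)

    def test_sinusoid_matches_analytic_derivative(self):
        t = np.arange(0, 10, 0.01)
        kin = bv.compute_kinematics(make_track(t, np.sin(t), np.zeros(t.size)),
                                    smooth_window=0.0)
        expected = np.abs(np.cos(t))
        interior = slice(5, -5)
        good = expected[interior] > 0.1  # avoid relative error near zeros
        rel = np.abs(kin.speed[interior][good] - expected[interior][good])
        assert np.max(rel / expected[interior][good]) < 0.01

    def test_static_mouse(self):
        t = np.arange(50) / 30.0
        kin = bv.compute_kinematics(make_track(t, np.full(50, 7.0), np.full(50, 3.0)))
        assert np.allclose(kin.speed, 0.0, atol=1e-12)

    def test_linearity_under_position_scaling(self, rng):
        t = np.arange(300) / 30.0
        x = np.cumsum(rng.standard_normal(300)) * 0.1
        y = np.cumsum(rng.standard_normal(300)) * 0.1
        k1 = bv.compute_kinematics(make_track(t, x, y))
        k3 = bv.compute_kinematics(make_track(t, 3 * x, 3 * y))
        assert np.allclose(k3.speed, 3 * k1.speed, atol=1e-9)
        assert np.allclose(k3.acceleration, 3 * k1.acceleration, atol=1e-9)

    def test_non_uniform_sampling_rejected(self):
        t = np.array([0.0, 0.033, 0.07, 0.1, 0.13])
        with pytest.raises(bv.BehaviorError):
            bv.compute_kinematics(make_track(t, t, t))


class TestTrigger:
    def _track_entering_at(self, t_entry, rate=30.0, total=360.0):
        t = np.arange(0, total, 1.0 / rate)
        x = np.full(t.size, 40.0)
        x[t >= t_entry] = 10.0  # inside the threat zone
        y = np.full(t.size, 10.0)
        return make_track(t, x, y)

    def test_scripted_entry(self):
        trig = bv.detect_trigger(self._track_entering_at(312.4), GEO)
        assert trig == pytest.approx(312.4, abs=1 / 30.0 + 1e-9)

    def test_already_inside_at_boundary(self):
        trig = bv.detect_trigger(self._track_entering_at(0.0), GEO)
        assert trig == pytest.approx(300.0, abs=1 / 30.0 + 1e-9)

    def test_never_enters(self):
        t = np.arange(0, 360, 1 / 30.0)
        track = make_track(t, np.full(t.size, 40.0), np.full(t.size, 10.0))
        with pytest.raises(bv.BehaviorError):
            bv.detect_trigger(track, GEO)


class TestEscape:
    def test_programmed_escape_recovered(self):
        behav = BehaviorSimParams(exploration_duration=60.0, post_duration=30.0,
                                  escape_latency=3.0, escape_peak_velocity=55.0,
                                  escape_peak_acceleration=360.0, seed=11)
        rec, track, train, gt = simulate_session(PhotometrySimParams(), behav)
        kin = bv.compute_kinematics(track)
        bout = bv.detect_escape(kin, track, train, GEO)
        assert bout is not None
        assert bout.latency == pytest.approx(gt.escape_latency, abs=0.2)
        assert bout.peak_velocity == pytest.approx(gt.peak_velocity, rel=0.05)
        assert bout.shelter_entry == pytest.approx(gt.shelter_entry, abs=0.2)

    def test_nonescaper_session_returns_none(self):
        behav = BehaviorSimParams(exploration_duration=60.0, post_duration=30.0,
                                  escapes=False, seed=4)
        rec, track, train, gt = simulate_session(PhotometrySimParams(), behav)
        kin = bv.compute_kinematics(track)
        assert bv.detect_escape(kin, track, train, GEO) is None
        assert not bv.classify_escaper(None)

    def test_mouse_in_shelter_at_onset_is_invalid(self, caplog):
        t = np.arange(0, 40, 1 / 30.0)
        x = np.full(t.size, 56.0)  # inside the shelter
        track = make_track(t, x, np.full(t.size, 10.0))
        kin = bv.compute_kinematics(track)
        train = loom_schedule(LoomParams(), 20.0)
        with caplog.at_level("WARNING"):
            assert bv.detect_escape(kin, track, train, GEO) is None
        assert "invalid" in caplog.text


class TestMovementBouts:
    def test_scripted_bout_recovered_from_simulation(self):
        behav = BehaviorSimParams(exploration_duration=60.0, post_duration=30.0,
                                  seed=3)
        rec, track, train, gt = simulate_session(PhotometrySimParams(), behav)
        kin = bv.compute_kinematics(track)
        bouts = bv.detect_movement_bouts(kin, (0.0, gt.trigger_time - 2.0))
        hit = [b for b in bouts if b.start <= gt.movement_bout_time <= b.end]
        assert len(hit) == 1
        assert hit[0].peak_velocity == pytest.approx(gt.movement_bout_peak,
                                                     rel=0.05)

    def test_no_motion_no_bouts(self):
        t = np.arange(0, 30, 1 / 30.0)
        kin = bv.KinematicsTrace(time=t, speed=np.zeros(t.size),
                                 acceleration=np.zeros(t.size), smooth_window=0.0)
        assert bv.detect_movement_bouts(kin, (0.0, 29.0)) == []

    def test_nearby_bouts_merged(self):
        t = np.arange(0, 10, 1 / 30.0)
        speed = np.zeros(t.size)
        speed[(t >= 2.0) & (t < 3.0)] = 25.0
        speed[(t >= 3.3) & (t < 4.0)] = 25.0  # 0.3 s gap -> merged
        kin = bv.KinematicsTrace(time=t, speed=speed,
                                 acceleration=np.zeros(t.size), smooth_window=0.0)
        bouts = bv.detect_movement_bouts(kin, (0.0, 9.9))
        assert len(bouts) == 1
        assert bouts[0].start == pytest.approx(2.0, abs=0.05)
        assert bouts[0].end == pytest.approx(4.0, abs=0.1)

    def test_empty_window_rejected(self):
        t = np.arange(0, 10, 1 / 30.0)
        kin = bv.KinematicsTrace(time=t, speed=np.zeros(t.size),
                                 acceleration=np.zeros(t.size), smooth_window=0.0)
        with pytest.raises(bv.BehaviorError):
            bv.detect_movement_bouts(kin, (20.0, 30.0))


class TestFreezing:
    def _kin_track(self, speed_fn, x_val):
        t = np.arange(0, 20, 1 / 30.0)
        speed = speed_fn(t)
        kin = bv.KinematicsTrace(time=t, speed=speed,
                                 acceleration=np.zeros(t.size), smooth_window=0.0)
        track = make_track(t, np.full(t.size, x_val), np.full(t.size, 10.0))
        return kin, track

    def test_scripted_immobility_outside_shelter(self):
        kin, track = self._kin_track(
            lambda t: np.where((t >= 5.0) & (t <= 7.0), 0.2, 5.0), 30.0)
        bouts = bv.detect_freezing(kin, track, (0.0, 19.9), GEO)
        assert len(bouts) == 1
        assert bouts[0].end - bouts[0].start == pytest.approx(2.0, abs=0.1)
        assert bouts[0].mean_speed < 1.0

    def test_continuous_locomotion_has_no_freezes(self):
        kin, track = self._kin_track(lambda t: np.full(t.size, 8.0), 30.0)
        assert bv.detect_freezing(kin, track, (0.0, 19.9), GEO) == []

    def test_immobility_inside_shelter_excluded(self):
        kin, track = self._kin_track(lambda t: np.full(t.size, 0.1), 56.0)
        assert bv.detect_freezing(kin, track, (0.0, 19.9), GEO) == []


class TestResamplingStability:
    def test_onset_agrees_between_30_and_60_hz(self):
        """The same continuous escape trajectory sampled at 30 and 60 Hz
        yields onsets within one 30 Hz sample."""
        def build(rate):
            t = np.arange(0, 40, 1.0 / rate)
            x = np.full(t.size, 15.0)
            # raised-cosine ramp to 50 cm/s starting at t = 24.0
            t_on, v, t1 = 24.0, 50.0, 0.4
            rel = np.clip((t - t_on) / t1, 0.0, None)
            speed = np.where(rel < 1.0, v * np.sin(0.5 * np.pi * rel) ** 2, v)
            speed[t < t_on] = 0.0
            dx = np.cumsum(speed) / rate
            xx = np.clip(x + dx, None, 60.5)
            return make_track(t, xx, np.full(t.size, 10.0))

        onsets = {}
        train = loom_schedule(LoomParams(), 20.0)
        for rate in (30.0, 60.0):
            track = build(rate)
            kin = bv.compute_kinematics(track)
            bout = bv.detect_escape(kin, track, train, GEO)
            assert bout is not None
            onsets[rate] = bout.onset
        assert abs(onsets[30.0] - onsets[60.0]) <= 1 / 30.0 + 1e-9


class TestGeometry:
    def test_zone_membership(self):
        assert GEO.in_threat_zone(10.0, 10.0)
        assert not GEO.in_threat_zone(30.0, 10.0)
        assert GEO.in_shelter(56.0, 10.0)
        assert not GEO.in_shelter(40.0, 10.0)

    def test_overlapping_zones_rejected(self):
        with pytest.raises(ValueError):
            bv.ArenaGeometry(length=25.0)

    def test_positions_outside_arena_rejected(self):
        t = np.arange(10) / 30.0
        with pytest.raises(bv.BehaviorError):
            make_track(t, np.full(10, 70.0), np.full(10, 10.0), geometry=GEO)
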