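"""Trajectory kinematics and behavioral event segmentation.

The arena is a 61 x 20.3 cm rectangle with a shelter at one end and a
20 x 20 cm threat zone at the opposite end, underneath the overhead display.
Coordinates are in the arena frame: origin at a threat-zone-end corner, x
along the long axis (so the threat zone occupies small x and the shelter
large x), units cm.

Segmentation covers the three behaviors the assay quantifies: stimulus-evoked
escape to shelter (latency + vigor), vigorous spontaneous movement bouts
during exploration, and freezing.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

logger = logging.getLogger(__name__)

__all__ = [
    "BehaviorError",
    "ArenaGeometry",
    "TrackingTrace",
    "KinematicsTrace",
    "EscapeBout",
    "MovementBout",
    "FreezeBout",
    "compute_kinematics",
    "detect_trigger",
    "detect_escape",
    "detect_movement_bouts",
    "detect_freezing",
    "classify_escaper",
]


class BehaviorError(ValueError):
    """Invalid tracking input or absent behavioral event."""


@dataclass(frozen=True)
class ArenaGeometry:
    """Arena with threat zone at x in [0, threat_zone_size] and shelter at
    x in [length - shelter_depth, length]."""

    length: float = 61.0          # cm
    width: float = 20.3           # cm
    shelter_depth: float = 10.0   # cm
    threat_zone_size: float = 20.0  # cm (square section, clipped to arena width)

    def __post_init__(self) -> None:
        for name in ("length", "width", "shelter_depth", "threat_zone_size"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite")
        if self.threat_zone_size + self.shelter_depth >= self.length:
            raise ValueError("threat zone and shelter overlap: zones must be "
                             "disjoint and inside the arena")

    @property
    def shelter_x(self) -> float:
        """x coordinate of the shelter boundary."""
        return self.length - self.shelter_depth

    def in_threat_zone(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x <= self.threat_zone_size) & (y <= min(self.threat_zone_size, self.width))

    def in_shelter(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return x >= self.shelter_x

    def contains(self, x, y, tol: float = 0.5) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return ((x >= -tol) & (x <= self.length + tol)
                & (y >= -tol) & (y <= self.width + tol))


@dataclass
class TrackingTrace:
    """Centroid trajectory (time s; x, y cm in the arena frame)."""

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    geometry: ArenaGeometry | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.time.size == self.x.size == self.y.size):
            raise BehaviorError("time, x and y must have equal length")
        if self.time.size < 2:
            raise BehaviorError("tracking must contain at least 2 samples")
        if np.any(np.diff(self.time) <= 0):
            raise BehaviorError("time must be strictly increasing")
        if self.geometry is not None:
            ok = self.geometry.contains(self.x, self.y)
            if not ok.all():
                i = int(np.flatnonzero(~ok)[0])
                raise BehaviorError(
                    f"position outside arena at sample {i}: "
                    f"({self.x[i]:.2f}, {self.y[i]:.2f})")

    @property
    def rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))


@dataclass
class KinematicsTrace:
    """Speed and (signed) acceleration derived from a smoothed trajectory."""

    time: np.ndarray
    speed: np.ndarray          # cm/s, >= 0
    acceleration: np.ndarray   # cm/s^2, d(speed)/dt
    smooth_window: float       # s, recorded for provenance


def compute_kinematics(track: TrackingTrace, smooth_window: float = 0.2) -> KinematicsTrace:
    """Differentiate the (optionally smoothed) trajectory.

    Position is smoothed with a centered moving average of ``smooth_window``
    s, then speed is the magnitude of the centered finite-difference velocity
    (one-sided at the endpoints) and acceleration the centered difference of
    speed.  Sampling must be uniform to 1%.
    """
    t = track.time
    if t.size < 3:
        raise BehaviorError("need at least 3 samples to differentiate")
    dt = np.diff(t)
    med = float(np.median(dt))
    if np.any(np.abs(dt - med) > 0.01 * med):
        raise BehaviorError("non-uniform sampling beyond 1% tolerance")
    rate = 1.0 / med
    w = int(round(smooth_window * rate))
    if w > 1:
        if w % 2 == 0:
            w += 1  # keep the average centered
        xs = uniform_filter1d(track.x, size=w, mode="nearest")
        ys = uniform_filter1d(track.y, size=w, mode="nearest")
    else:
        xs, ys = track.x, track.y
    vx = np.gradient(xs, t)
    vy = np.gradient(ys, t)
    speed = np.hypot(vx, vy)
    accel = np.gradient(speed, t)
    return KinematicsTrace(time=t, speed=speed, acceleration=accel,
                           smooth_window=smooth_window)


def detect_trigger(track: TrackingTrace, geometry: ArenaGeometry,
                   exploration_min: float = 300.0) -> float:
    """Time of the first sample at or after ``exploration_min`` with the
    mouse inside the threat zone (the stimulus trigger rule)."""
    if track.time[-1] <= exploration_min:
        raise BehaviorError("track shorter than the exploration period")
    mask = (track.time >= exploration_min) & geometry.in_threat_zone(track.x, track.y)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise BehaviorError("mouse never enters the threat zone after the "
                            "exploration period; no trigger")
    return float(track.time[idx[0]])


@dataclass(frozen=True)
class EscapeBout:
    """Stimulus-evoked flight to shelter."""

    onset: float            # s, movement onset
    latency: float          # s from first disk onset
    peak_velocity: float    # cm/s between onset and shelter entry
    peak_acceleration: float  # cm/s^2
    shelter_entry: float    # s

    def __post_init__(self) -> None:
        if self.onset > self.shelter_entry:
            raise ValueError("escape onset must precede shelter entry")
        if self.latency <= 0:
            raise ValueError("escape latency must be > 0")


@dataclass(frozen=True)
class MovementBout:
    start: float
    end: float
    peak_velocity: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("bout end must follow its start")


@dataclass(frozen=True)
class FreezeBout:
    start: float
    end: float
    mean_speed: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("bout end must follow its start")


def detect_escape(kin: KinematicsTrace, track: TrackingTrace, train,
                  geometry: ArenaGeometry,
                  onset_threshold: float = 10.0,
                  sustain: float = 0.2,
                  escape_window: float = 10.0) -> EscapeBout | None:
    """Segment the escape evoked by a stimulus train, if any.

    The bout onset is the first time after disk-1 onset at which speed
    exceeds ``onset_threshold`` cm/s for at least ``sustain`` s, provided the
    mouse subsequently crosses the shelter boundary within ``escape_window``
    s of disk-1 onset.  Returns None for non-escapers, and None (flagged in
    the log) when the mouse is already sheltered at stimulus onset.
    """
    t0 = float(train.disk_onsets[0])
    if kin.time[-1] < t0 + escape_window:
        raise BehaviorError("trace must cover the escape window after the train")
    i0 = int(np.searchsorted(track.time, t0, side="right"))
    if i0 >= track.time.size:
        raise BehaviorError("stimulus train lies past the end of the track")
    if bool(geometry.in_shelter(track.x[i0], track.y[i0])):
        logger.warning("mouse already in shelter at disk onset; trial invalid")
        return None
    sheltered = geometry.in_shelter(track.x, track.y) & (track.time > t0)
    entry_idx = np.flatnonzero(sheltered)
    if entry_idx.size == 0:
        return None
    entry = float(track.time[entry_idx[0]])
    if entry > t0 + escape_window:
        return None
    rate = track.rate
    need = max(1, int(round(sustain * rate)))
    fast = (kin.speed >= onset_threshold) & (kin.time > t0) & (kin.time <= entry)
    # first run of >= `need` consecutive fast samples
    onset_i = None
    run = 0
    for i in np.flatnonzero((kin.time > t0) & (kin.time <= entry + sustain)):
        if kin.speed[i] >= onset_threshold:
            run += 1
            if run == 1:
                first = i
            if run >= need:
                onset_i = first
                break
        else:
            run = 0
    if onset_i is None:
        cand = np.flatnonzero(fast)
        if cand.size == 0:
            logger.warning("shelter reached without a supra-threshold movement "
                           "onset; no escape bout returned")
            return None
        onset_i = int(cand[0])
    onset = float(kin.time[onset_i])
    seg = (kin.time >= onset) & (kin.time <= entry)
    return EscapeBout(
        onset=onset,
        latency=onset - t0,
        peak_velocity=float(kin.speed[seg].max()),
        peak_acceleration=float(kin.acceleration[seg].max()),
        shelter_entry=entry,
    )


def _runs(mask: np.ndarray) -> list:
    """Maximal [start, stop) index runs of True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def detect_movement_bouts(kin: KinematicsTrace, window: tuple,
                          bout_floor: float = 2.0,
                          vigor_threshold: float = 20.0,
                          merge_gap: float = 0.5) -> list:
    """Vigorous spontaneous movement bouts within ``window``.

    Maximal intervals with speed >= ``bout_floor`` are merged across gaps
    shorter than ``merge_gap`` s and kept when they contain a peak of at
    least ``vigor_threshold`` cm/s.
    """
    sel = (kin.time >= window[0]) & (kin.time <= window[1])
    if not sel.any():
        raise BehaviorError(f"empty analysis window {window}")
    t = kin.time[sel]
    v = kin.speed[sel]
    runs = _runs(v >= bout_floor)
    merged = []
    for s, e in runs:
        if merged and t[s] - t[merged[-1][1] - 1] < merge_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    out = []
    for s, e in merged:
        peak = float(v[s:e].max())
        if peak >= vigor_threshold:
            out.append(MovementBout(start=float(t[s]), end=float(t[e - 1]),
                                    peak_velocity=peak))
    return out


def detect_freezing(kin: KinematicsTrace, track: TrackingTrace, window: tuple,
                    geometry: ArenaGeometry,
                    freeze_ceiling: float = 1.0,
                    min_duration: float = 1.0) -> list:
    """Freezing bouts: immobility (speed < ``freeze_ceiling``) sustained at
    least ``min_duration`` s, entirely outside the shelter."""
    sel = (kin.time >= window[0]) & (kin.time <= window[1])
    if not sel.any():
        raise BehaviorError(f"empty analysis window {window}")
    t = kin.time[sel]
    v = kin.speed[sel]
    outside = ~geometry.in_shelter(track.x[sel], track.y[sel])
    out = []
    for s, e in _runs((v < freeze_ceiling) & outside):
        if t[e - 1] - t[s] >= min_duration:
            out.append(FreezeBout(start=float(t[s]), end=float(t[e - 1]),
                                  mean_speed=float(v[s:e].mean())))
    return out


def classify_escaper(escape: EscapeBout | None) -> bool:
    """A mouse counts as an escaper iff its threat trial produced an escape bout."""
    return escape is not None
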