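"""Two-channel fiber-photometry preprocessing and event-aligned analysis.

The recording carries a signal channel (465 nm excitation, dopamine-sensitive
dLight1 fluorescence) and an isosbestic reference channel (405 nm excitation,
dopamine-independent).  Motion artifacts and photobleaching appear in both
channels, so a first-order (straight line) least-squares fit of the reference
to the signal, subtracted from the signal, yields an artifact-corrected dF
trace.  dF is z-scored within a user-chosen epoch; transient amplitudes are
reported in those z units.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal

logger = logging.getLogger(__name__)

__all__ = [
    "PhotometryError",
    "DegenerateFitError",
    "PhotometryRecording",
    "CorrectedTrace",
    "PeakEvent",
    "EventAlignedMatrix",
    "isosbestic_correct",
    "lowpass",
    "lowpass_recording",
    "zscore_epoch",
    "detect_peaks",
    "window_response",
    "baseline_peak",
    "align_to_events",
    "stimulus_response",
]


class PhotometryError(ValueError):
    """Invalid photometry input."""


class DegenerateFitError(PhotometryError):
    """Reference channel carries no variance; the correction fit is underdetermined."""


@dataclass
class PhotometryRecording:
    """Raw two-channel recording on a uniform time grid.

    ``event_times`` maps labels ("trigger", "disk1", ...) to timestamps in
    seconds on the same clock as ``time``.
    """

    time: np.ndarray
    f465: np.ndarray
    f405: np.ndarray
    sampling_rate: float
    event_times: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.f465 = np.asarray(self.f465, dtype=float)
        self.f405 = np.asarray(self.f405, dtype=float)
        n = self.time.size
        if self.f465.size != n or self.f405.size != n:
            raise PhotometryError("time, f465 and f405 must have equal length")
        if n < 2:
            raise PhotometryError("recording must contain at least 2 samples")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise PhotometryError("time must be strictly increasing")
        if not self.sampling_rate > 0:
            raise PhotometryError("sampling_rate must be > 0")
        nominal = 1.0 / self.sampling_rate
        if abs(np.median(dt) - nominal) > 1e-6 * nominal:
            raise PhotometryError(
                "sampling_rate inconsistent with the time grid "
                f"(median dt {np.median(dt):.6g}, expected {nominal:.6g})")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass
class CorrectedTrace:
    """Artifact-corrected trace: dF stage and (after z-scoring) z stage."""

    time: np.ndarray
    dff: np.ndarray
    fit_slope: float
    fit_intercept: float
    sampling_rate: float
    z: np.ndarray | None = None
    epoch_window: tuple | None = None

    @property
    def values(self) -> np.ndarray:
        """z if available, else dF."""
        return self.z if self.z is not None else self.dff


@dataclass(frozen=True)
class PeakEvent:
    """A detected transient peak.

    ``latency`` is measured from the peak's reference event (stimulus onset,
    window start, ...), so ``time - latency`` recovers the reference time.
    """

    time: float
    amplitude: float
    latency: float
    reference_label: str = ""


@dataclass
class EventAlignedMatrix:
    """Event-aligned traces on a common relative-time grid (one row per event)."""

    relative_time: np.ndarray
    values: np.ndarray  # shape (n_events, n_samples)
    event_times: tuple
    mean: np.ndarray = field(init=False)
    sem: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.mean = self.values.mean(axis=0)
        n = self.values.shape[0]
        if n > 1:
            self.sem = self.values.std(axis=0, ddof=1) / math.sqrt(n)
        else:
            self.sem = np.zeros_like(self.mean)

    @property
    def n_events(self) -> int:
        return self.values.shape[0]


def isosbestic_correct(rec: PhotometryRecording) -> CorrectedTrace:
    """Fit the 405 nm reference to the 465 nm signal with a first-order
    polynomial (OLS) and subtract the fitted model: dF = f465 - (a*f405 + b).

    Raises :class:`DegenerateFitError` when the reference is (near-)constant
    and :class:`PhotometryError` on NaN samples (naming the first offending
    index).
    """
    if rec.time.size < 10:
        raise PhotometryError("need at least 10 samples for the correction fit")
    for name, arr in (("f465", rec.f465), ("f405", rec.f405)):
        bad = np.flatnonzero(~np.isfinite(arr))
        if bad.size:
            raise PhotometryError(f"non-finite sample in {name} at index {bad[0]}")
    ref = rec.f405
    scale = max(1.0, float(np.abs(ref).mean()))
    if float(ref.std()) < 1e-9 * scale:
        raise DegenerateFitError("reference channel is constant; slope is underdetermined")
    slope, intercept = np.polyfit(ref, rec.f465, 1)
    dff = rec.f465 - (slope * ref + intercept)
    return CorrectedTrace(
        time=rec.time, dff=dff, fit_slope=float(slope),
        fit_intercept=float(intercept), sampling_rate=rec.sampling_rate)


def lowpass_recording(rec: PhotometryRecording, cutoff: float,
                      order: int = 2) -> PhotometryRecording:
    """Zero-phase Butterworth low-pass of both raw channels.

    Band-limiting before the correction fit suppresses the regression
    attenuation that per-channel detector noise induces in the reference
    slope (errors-in-variables); because the filter is linear it commutes
    with the channel subtraction itself.
    """
    nyq = rec.sampling_rate / 2.0
    if not (0 < cutoff < nyq):
        raise PhotometryError(f"cutoff must lie in (0, {nyq}) Hz")
    sos = _signal.butter(order, cutoff, btype="low", fs=rec.sampling_rate, output="sos")
    return PhotometryRecording(
        time=rec.time, f465=_signal.sosfiltfilt(sos, rec.f465),
        f405=_signal.sosfiltfilt(sos, rec.f405),
        sampling_rate=rec.sampling_rate, event_times=dict(rec.event_times))


def lowpass(trace: CorrectedTrace, cutoff: float, order: int = 2) -> CorrectedTrace:
    """Zero-phase Butterworth low-pass of the dF trace.

    Band-limits detector noise before z-scoring and peak detection; ``cutoff``
    in Hz must lie below the Nyquist frequency.  Returns a new trace (the z
    stage, if any, is discarded and must be recomputed).
    """
    nyq = trace.sampling_rate / 2.0
    if not (0 < cutoff < nyq):
        raise PhotometryError(f"cutoff must lie in (0, {nyq}) Hz")
    sos = _signal.butter(order, cutoff, btype="low", fs=trace.sampling_rate, output="sos")
    dff = _signal.sosfiltfilt(sos, trace.dff)
    return replace(trace, dff=dff, z=None, epoch_window=None)


def zscore_epoch(trace: CorrectedTrace, window: tuple) -> CorrectedTrace:
    """z-score the whole dF trace using mean and sample SD (n-1 denominator)
    computed from the samples inside ``window`` (inclusive bounds, s)."""
    start, end = float(window[0]), float(window[1])
    mask = (trace.time >= start) & (trace.time <= end)
    n = int(mask.sum())
    if n < 3:
        raise PhotometryError(f"epoch window [{start}, {end}] contains {n} < 3 samples")
    seg = trace.dff[mask]
    mu = float(seg.mean())
    sd = float(seg.std(ddof=1))
    if sd < 1e-12 * max(1.0, abs(mu)):
        raise PhotometryError("dF is constant within the epoch window; z-score undefined")
    z = (trace.dff - mu) / sd
    return replace(trace, z=z, epoch_window=(start, end))


def _search_slice(time: np.ndarray, window: tuple) -> slice:
    i0, i1 = np.searchsorted(time, [float(window[0]), float(window[1])])
    return slice(int(i0), int(i1))


def detect_peaks(trace: CorrectedTrace, search_window: tuple,
                 min_prominence: float = 0.5,
                 min_separation: float = 0.25) -> list:
    """Local maxima in ``search_window`` with at least ``min_prominence``
    (z units) and ``min_separation`` (s) between peaks, sorted by time.

    Plateau ties are broken to the earliest sample.  Latency is reported
    relative to the window start.
    """
    sl = _search_slice(trace.time, search_window)
    if sl.stop - sl.start < 1:
        raise PhotometryError(f"empty search window {search_window}")
    x = trace.values[sl]
    distance = max(1, int(round(min_separation * trace.sampling_rate)))
    idx, props = _signal.find_peaks(
        x, prominence=min_prominence, distance=distance, plateau_size=(1, None))
    # earliest sample of each plateau, not its midpoint
    idx = props["left_edges"]
    t0 = float(search_window[0])
    out = []
    for i in idx:
        t = float(trace.time[sl.start + i])
        out.append(PeakEvent(time=t, amplitude=float(x[i]), latency=t - t0,
                             reference_label="window_start"))
    return out


def window_response(trace: CorrectedTrace, window: tuple,
                    min_prominence: float = 0.5,
                    min_separation: float = 0.25,
                    reference_label: str = "") -> tuple:
    """Largest peak in ``window``: the biggest qualifying local maximum, or
    the window maximum sample when no local maximum qualifies or when the
    response culminates at the window boundary (both logged as fallbacks).

    The boundary rule keeps the statistic faithful when a transient peaks at
    the very edge of the window — the window's own maximum is then a better
    estimate of the response than a smaller interior bump.

    Returns ``(PeakEvent, used_fallback)``; the event's latency is measured
    from the window start.
    """
    peaks = detect_peaks(trace, window, min_prominence, min_separation)
    t0 = float(window[0])
    sl = _search_slice(trace.time, window)
    x = trace.values[sl]
    i = int(np.argmax(x))
    win_max = float(x[i])
    if peaks:
        best = max(peaks, key=lambda p: p.amplitude)
        if best.amplitude + 1e-12 >= win_max:
            ev = PeakEvent(time=best.time, amplitude=best.amplitude,
                           latency=best.time - t0,
                           reference_label=reference_label)
            return ev, False
        logger.info("window [%.3f, %.3f]: maximum lies at the boundary above "
                    "every interior peak; using the window maximum sample",
                    t0, window[1])
    else:
        logger.info("no local maximum in window [%.3f, %.3f]; falling back to "
                    "the window maximum sample", t0, window[1])
    t = float(trace.time[sl.start + i])
    ev = PeakEvent(time=t, amplitude=win_max, latency=t - t0,
                   reference_label=reference_label)
    return ev, True


def baseline_peak(trace: CorrectedTrace, stimulus_onset: float,
                  baseline_duration: float = 1.0,
                  min_prominence: float = 0.5,
                  min_separation: float = 0.25) -> float:
    """Amplitude of the largest peak in the 1-s epoch immediately before
    stimulus onset — the prestimulus baseline against which evoked transients
    are compared.  Falls back to the window maximum sample when no local
    maximum qualifies (logged)."""
    if stimulus_onset - baseline_duration < trace.time[0]:
        raise PhotometryError(
            "stimulus onset lies within the first baseline_duration of the trace")
    ev, _ = window_response(
        trace, (stimulus_onset - baseline_duration, stimulus_onset),
        min_prominence, min_separation, reference_label="baseline")
    return ev.amplitude


def align_to_events(trace: CorrectedTrace, events, pre: float,
                    post: float) -> EventAlignedMatrix:
    """Extract one row per event, ``pre`` s before to ``post`` s after, on a
    common relative grid (nearest-sample indexing, no interpolation).

    Events without full pre/post coverage are dropped with a log entry;
    if none survive, a :class:`PhotometryError` is raised.
    """
    fs = trace.sampling_rate
    n_pre = int(round(pre * fs))
    n_post = int(round(post * fs))
    rel = np.arange(-n_pre, n_post + 1) / fs
    x = trace.values
    n = x.size
    rows, kept = [], []
    for e in events:
        i = int(round((float(e) - trace.time[0]) * fs))
        if i - n_pre < 0 or i + n_post >= n:
            logger.info("event at %.3f s dropped: incomplete pre/post coverage", float(e))
            continue
        rows.append(x[i - n_pre: i + n_post + 1])
        kept.append(float(e))
    if not rows:
        raise PhotometryError("no events survive the pre/post coverage check")
    return EventAlignedMatrix(relative_time=rel, values=np.vstack(rows),
                              event_times=tuple(kept))


def stimulus_response(trace: CorrectedTrace, train, response_window: float = 1.0,
                      min_prominence: float = 0.5,
                      min_separation: float = 0.25) -> tuple:
    """Per-disk evoked responses plus the prestimulus baseline amplitude.

    For each disk onset the largest peak within ``response_window`` s of the
    onset is returned as a :class:`PeakEvent` labelled ``disk1..diskN`` whose
    latency is measured from that onset; the baseline is the largest-peak
    amplitude in the 1 s before disk 1.  The default 1.0 s window brackets the
    sub-second evoked peak latencies of the sensor.
    """
    if train.disk_onsets[-1] + response_window > trace.time[-1] + 1e-9:
        raise PhotometryError("stimulus train extends past the end of the trace")
    events = []
    for k, onset in enumerate(train.disk_onsets):
        ev, _ = window_response(
            trace, (onset, onset + response_window), min_prominence,
            min_separation, reference_label=f"disk{k + 1}")
        events.append(ev)
    base = baseline_peak(trace, train.disk_onsets[0],
                         min_prominence=min_prominence,
                         min_separation=min_separation)
    return events, base
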