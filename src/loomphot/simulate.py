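"""Synthetic looming-assay sessions with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* a 465 nm signal channel = baseline + exponential photobleaching + a shared
  low-pass (Ornstein-Uhlenbeck) motion artifact + a train of convolved
  dopamine transients + white detector noise;
* a 405 nm isosbestic reference = baseline + bleaching + the *same* artifact
  realization + independent white noise, with no transients;
* a mouse trajectory in the 61 x 20.3 cm arena: Ornstein-Uhlenbeck
  exploration with one scripted vigorous movement bout, a threat-zone
  approach that triggers a five-disk looming train, a stimulus-arrest dwell,
  and (for escapers) a raised-cosine escape ramp to the shelter;
* a programmable linear coupling, with Gaussian residuals, between the
  first-disk transient amplitude and the escape latency / peak velocity /
  peak acceleration.

Every programmed quantity is recorded in a :class:`SessionGroundTruth` so
the downstream pipeline can be validated end to end.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal

from .behavior import ArenaGeometry, TrackingTrace
from .photometry import PhotometryRecording
from .stimulus import LoomParams, StimulusTrain, loom_schedule

__all__ = [
    "PhotometrySimParams",
    "BehaviorSimParams",
    "CouplingParams",
    "SessionGroundTruth",
    "CohortGroundTruth",
    "transient_kernel",
    "kernel_peak_time",
    "kernel_energy",
    "z_unit_scale",
    "residual_sd_for_r_squared",
    "draw_coupling",
    "simulate_photometry",
    "simulate_session",
    "simulate_cohort",
]

# White-noise SD pass-through of the default analysis band-limit (2nd-order
# zero-phase Butterworth, 1.5 Hz cutoff at 100 Hz sampling).  Used only to
# express injected transient amplitudes in nominal z units of the corrected,
# band-limited trace.
_ZSCALE_FILTER_FACTOR = 0.158


def _positive(name: str, v: float) -> None:
    if not (math.isfinite(v) and v > 0):
        raise ValueError(f"{name} must be positive and finite, got {v}")


def _nonneg(name: str, v: float) -> None:
    if not (math.isfinite(v) and v >= 0):
        raise ValueError(f"{name} must be >= 0 and finite, got {v}")


@dataclass(frozen=True)
class PhotometrySimParams:
    """Two-channel photometry generative parameters (fluorescence in a.u.)."""

    sampling_rate: float = 100.0   # Hz
    duration: float = 30.0         # s
    baseline_465: float = 100.0
    baseline_405: float = 80.0
    bleach_amplitude_465: float = 8.0
    bleach_amplitude_405: float = 8.0
    bleach_tau_465: float = 1200.0  # s
    bleach_tau_405: float = 1200.0  # s
    artifact_sd: float = 1.0        # a.u., stationary SD of the shared artifact
    artifact_tau: float = 0.5       # s, artifact autocorrelation time
    rise_tau: float = 0.1           # s, transient kernel rise
    decay_tau: float = 0.8          # s, transient kernel decay
    transient_times: tuple = ()     # s
    transient_amplitudes: tuple = ()  # a.u., kernel peak height
    white_noise_sd: float = 0.2     # a.u., per-channel detector noise
    spontaneous_rate: float = 0.1   # Hz, Poisson rate of spontaneous release events
    spontaneous_amplitude_z: float = 1.0  # nominal z, exponential mean amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        _positive("sampling_rate", self.sampling_rate)
        _positive("duration", self.duration)
        for name in ("bleach_tau_465", "bleach_tau_405", "artifact_tau",
                     "rise_tau", "decay_tau"):
            _positive(name, getattr(self, name))
        for name in ("baseline_465", "baseline_405", "bleach_amplitude_465",
                     "bleach_amplitude_405", "artifact_sd", "white_noise_sd",
                     "spontaneous_rate", "spontaneous_amplitude_z"):
            _nonneg(name, getattr(self, name))
        if self.decay_tau <= self.rise_tau:
            raise ValueError("decay_tau must exceed rise_tau")
        times = tuple(float(t) for t in self.transient_times)
        amps = tuple(float(a) for a in self.transient_amplitudes)
        object.__setattr__(self, "transient_times", times)
        object.__setattr__(self, "transient_amplitudes", amps)
        if len(times) != len(amps):
            raise ValueError("transient_times and transient_amplitudes must "
                             "have equal length")
        for t in times:
            if not (0.0 <= t < self.duration):
                raise ValueError(f"transient time {t} outside [0, duration)")
        for a in amps:
            _nonneg("transient amplitude", a)


@dataclass(frozen=True)
class BehaviorSimParams:
    """Behavioral script parameters.

    ``escape_latency`` / ``escape_peak_velocity`` / ``escape_peak_acceleration``
    are the programmed values used when no :class:`CouplingParams` is supplied;
    with coupling they are drawn per session from the coupling model instead.
    """

    arena: ArenaGeometry = field(default_factory=ArenaGeometry)
    tracking_rate: float = 30.0        # Hz
    exploration_duration: float = 300.0  # s before the trigger rule arms
    post_duration: float = 180.0       # s recorded after the trigger
    exploration_speed_scale: float = 8.0  # cm/s, OU velocity stationary SD
    exploration_tau: float = 1.0       # s, OU velocity correlation time
    movement_bout_peak: float = 30.0   # cm/s, scripted spontaneous bout
    approach_speed: float = 15.0       # cm/s walk into the threat zone
    escape_latency: float = 3.8        # s (used when no coupling is given)
    escape_peak_velocity: float = 56.0     # cm/s
    escape_peak_acceleration: float = 360.0  # cm/s^2
    min_escape_latency: float = 1.25  # s; keeps the stimulus and escape
    # transients temporally separate, as observed (escape follows the
    # stimulus-evoked peak by >= ~1 s in the assay)
    escapes: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tracking_rate", "exploration_duration", "post_duration",
                     "exploration_speed_scale", "exploration_tau",
                     "movement_bout_peak", "approach_speed",
                     "escape_peak_velocity", "escape_peak_acceleration"):
            _positive(name, getattr(self, name))
        if self.escapes and not self.escape_latency > 0:
            raise ValueError("escape_latency must be > 0 when escapes is true")


@dataclass(frozen=True)
class CouplingParams:
    """Linear coupling between first-disk transient amplitude (nominal z) and
    escape kinematics, with Gaussian residuals.

    Defaults program population means matching the assay's reported escape
    kinematics (latency ~3.8 s, peak velocity ~56 cm/s, acceleration
    ~360 cm/s^2 at the mean amplitude of 3 z) and population R^2 of 0.80 /
    0.71 / 0.73 for latency / velocity / acceleration.
    """

    latency_slope: float = -0.6       # s per z (larger transients -> earlier escape)
    latency_intercept: float = 5.6    # s
    latency_residual_sd: float = 0.45  # s
    velocity_slope: float = 5.5       # cm/s per z
    velocity_intercept: float = 39.5  # cm/s
    velocity_residual_sd: float = 5.3  # cm/s
    acceleration_slope: float = 38.0  # cm/s^2 per z
    acceleration_intercept: float = 251.0  # cm/s^2
    acceleration_residual_sd: float = 34.7  # cm/s^2
    amplitude_mean: float = 3.0       # nominal z units
    amplitude_sd: float = 1.5         # nominal z units
    escape_transient_mean: float = 2.0  # nominal z; 0 disables
    escape_transient_sd: float = 0.6

    def __post_init__(self) -> None:
        for name in ("latency_residual_sd", "velocity_residual_sd",
                     "acceleration_residual_sd", "amplitude_sd",
                     "escape_transient_sd"):
            _nonneg(name, getattr(self, name))
        _nonneg("amplitude_mean", self.amplitude_mean)


def residual_sd_for_r_squared(slope: float, amplitude_sd: float,
                              r_squared: float) -> float:
    """Residual SD that makes the programmed population R^2 equal
    ``r_squared`` for a linear coupling ``y = a + slope * amplitude + eps``."""
    if not (0 < r_squared <= 1):
        raise ValueError("r_squared must lie in (0, 1]")
    return abs(slope) * amplitude_sd * math.sqrt(1.0 / r_squared - 1.0)


@dataclass
class SessionGroundTruth:
    """Everything the generator injected, for downstream validation."""

    transient_times: tuple = ()
    transient_amplitudes: tuple = ()       # a.u.
    transient_amplitudes_z: tuple = ()     # nominal z units
    spontaneous_times: tuple = ()
    spontaneous_amplitudes: tuple = ()     # a.u.
    bleach_amplitude_465: float = 0.0
    bleach_amplitude_405: float = 0.0
    bleach_tau_465: float = 1.0
    bleach_tau_405: float = 1.0
    artifact_sd: float = 0.0
    stimulus_amplitude_z: float | None = None
    stimulus_transient_time: float | None = None
    trigger_time: float | None = None
    escapes: bool | None = None
    escape_onset: float | None = None
    escape_latency: float | None = None      # s from trigger (= disk-1 onset)
    shelter_entry: float | None = None
    peak_velocity: float | None = None       # cm/s, programmed
    peak_acceleration: float | None = None   # cm/s^2, programmed
    latency_clipped: bool = False
    movement_bout_time: float | None = None
    movement_bout_peak: float | None = None


@dataclass
class CohortGroundTruth:
    coupling: CouplingParams | None
    sessions: tuple       # of SessionGroundTruth
    escaper_flags: tuple  # of bool
    seeds: tuple          # (phot_seed, behav_seed) per mouse

    @property
    def amplitudes_z(self) -> np.ndarray:
        return np.array([g.stimulus_amplitude_z for g in self.sessions], dtype=float)

    @property
    def latencies(self) -> np.ndarray:
        return np.array([np.nan if g.escape_latency is None else g.escape_latency
                         for g in self.sessions], dtype=float)


def kernel_peak_time(rise_tau: float, decay_tau: float) -> float:
    """Time to peak of the difference-of-exponentials transient kernel."""
    return (rise_tau * decay_tau / (decay_tau - rise_tau)) * math.log(decay_tau / rise_tau)


def transient_kernel(t, rise_tau: float = 0.1, decay_tau: float = 0.8) -> np.ndarray:
    """Difference-of-exponentials kernel normalized to unit peak; 0 for t < 0."""
    t = np.asarray(t, dtype=float)
    tp = kernel_peak_time(rise_tau, decay_tau)
    norm = math.exp(-tp / decay_tau) - math.exp(-tp / rise_tau)
    out = np.where(t >= 0,
                   (np.exp(-np.clip(t, 0, None) / decay_tau)
                    - np.exp(-np.clip(t, 0, None) / rise_tau)) / norm,
                   0.0)
    return out


def kernel_energy(rise_tau: float, decay_tau: float) -> float:
    """Integral of the squared unit-peak transient kernel, in seconds."""
    r, d = rise_tau, decay_tau
    tp = kernel_peak_time(r, d)
    norm = math.exp(-tp / d) - math.exp(-tp / r)
    raw = d / 2.0 + r / 2.0 - 2.0 * (r * d / (r + d))
    return raw / (norm * norm)


def z_unit_scale(params: PhotometrySimParams) -> float:
    """a.u. of dF per nominal z unit of the corrected, band-limited trace.

    The baseline-epoch SD that defines a z unit has two parts: the fast
    residual (difference of the two channels' white noise, attenuated by the
    default 1.5 Hz analysis band-limit) and the slow variance contributed by
    spontaneous release events, whose amplitudes are themselves expressed in
    z units — giving the self-consistent scale

        sigma_total = sigma_fast / sqrt(1 - 2 * rate * mz^2 * Ek)

    with ``mz`` the mean spontaneous amplitude (exponential) and ``Ek`` the
    kernel energy.  Falls back to 1 a.u. for noise-free simulations.
    """
    sf = math.sqrt(2.0) * params.white_noise_sd * _ZSCALE_FILTER_FACTOR
    if sf == 0:
        return 1.0
    load = (2.0 * params.spontaneous_rate * params.spontaneous_amplitude_z ** 2
            * kernel_energy(params.rise_tau, params.decay_tau))
    if load >= 1.0:
        raise ValueError(
            "spontaneous-event variance load >= 1: reduce spontaneous_rate "
            "or spontaneous_amplitude_z")
    return sf / math.sqrt(1.0 - load)


def _ou_series(rng: np.random.Generator, n: int, sd: float, tau: float,
               dt: float) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck process sampled at dt (AR(1))."""
    if n <= 0:
        return np.empty(0)
    if sd == 0:
        return np.zeros(n)
    phi = math.exp(-dt / tau)
    eps = rng.standard_normal(n) * (sd * math.sqrt(1.0 - phi * phi))
    x0 = rng.standard_normal() * sd
    out, _ = _signal.lfilter([1.0], [1.0, -phi], eps, zi=np.array([phi * x0]))
    return out


def simulate_photometry(params: PhotometrySimParams):
    """Generate one two-channel recording.

    Both channels share the identical artifact realization; transients are
    added to the 465 channel only.  Reproducible bitwise for a fixed seed.
    Returns ``(PhotometryRecording, SessionGroundTruth)``.
    """
    rng = np.random.default_rng(params.seed)
    fs = params.sampling_rate
    n = int(round(params.duration * fs))
    t = np.arange(n) / fs
    dt = 1.0 / fs

    bleach465 = params.bleach_amplitude_465 * np.exp(-t / params.bleach_tau_465)
    bleach405 = params.bleach_amplitude_405 * np.exp(-t / params.bleach_tau_405)
    artifact = _ou_series(rng, n, params.artifact_sd, params.artifact_tau, dt)

    times = list(params.transient_times)
    amps = list(params.transient_amplitudes)
    sp_times: np.ndarray = np.empty(0)
    sp_amps: np.ndarray = np.empty(0)
    if params.spontaneous_rate > 0 and params.spontaneous_amplitude_z > 0:
        zscale = z_unit_scale(params)
        n_spont = rng.poisson(params.spontaneous_rate * params.duration)
        sp_times = np.sort(rng.uniform(0, params.duration, size=n_spont))
        sp_amps = rng.exponential(params.spontaneous_amplitude_z * zscale,
                                  size=n_spont)
        times += list(sp_times)
        amps += list(sp_amps)

    transients = np.zeros(n)
    for ti, ai in zip(times, amps):
        i0 = int(np.ceil(ti * fs))
        if i0 >= n:
            continue
        transients[i0:] += ai * transient_kernel(
            t[i0:] - ti, params.rise_tau, params.decay_tau)

    noise465 = rng.standard_normal(n) * params.white_noise_sd
    noise405 = rng.standard_normal(n) * params.white_noise_sd

    f465 = params.baseline_465 + bleach465 + artifact + transients + noise465
    f405 = params.baseline_405 + bleach405 + artifact + noise405

    rec = PhotometryRecording(time=t, f465=f465, f405=f405, sampling_rate=fs)
    gt = SessionGroundTruth(
        transient_times=tuple(times),
        transient_amplitudes=tuple(amps),
        transient_amplitudes_z=tuple(a / z_unit_scale(params) for a in amps),
        spontaneous_times=tuple(float(t) for t in sp_times),
        spontaneous_amplitudes=tuple(float(a) for a in sp_amps),
        bleach_amplitude_465=params.bleach_amplitude_465,
        bleach_amplitude_405=params.bleach_amplitude_405,
        bleach_tau_465=params.bleach_tau_465,
        bleach_tau_405=params.bleach_tau_405,
        artifact_sd=params.artifact_sd,
    )
    return rec, gt


def draw_coupling(coupling: CouplingParams, rng: np.random.Generator):
    """One session's draw from the coupling model.

    Returns ``(amplitude_z, latency, peak_velocity, peak_acceleration,
    escape_transient_z)``; the amplitude is truncated at 0.2 z.
    """
    amp_z = max(0.2, rng.normal(coupling.amplitude_mean, coupling.amplitude_sd))
    latency = (coupling.latency_intercept + coupling.latency_slope * amp_z
               + rng.normal(0.0, coupling.latency_residual_sd))
    v_peak = (coupling.velocity_intercept + coupling.velocity_slope * amp_z
              + rng.normal(0.0, coupling.velocity_residual_sd))
    a_peak = (coupling.acceleration_intercept
              + coupling.acceleration_slope * amp_z
              + rng.normal(0.0, coupling.acceleration_residual_sd))
    esc_amp_z = (max(0.0, rng.normal(coupling.escape_transient_mean,
                                     coupling.escape_transient_sd))
                 if coupling.escape_transient_mean > 0 else 0.0)
    return amp_z, latency, v_peak, a_peak, esc_amp_z


def _fold(p: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect an unconstrained path into [lo, hi] (preserves |dp/dt|)."""
    span = hi - lo
    q = np.mod(p - lo, 2.0 * span)
    return lo + np.where(q > span, 2.0 * span - q, q)


def _raised_cos_ramp(n: int, peak: float, up: bool) -> np.ndarray:
    """n-sample raised-cosine speed ramp 0 -> peak (up) or peak -> 0."""
    x = np.arange(1, n + 1) / n
    prof = peak * np.sin(0.5 * math.pi * x) ** 2
    return prof if up else prof[::-1]


def simulate_session(phot: PhotometrySimParams, behav: BehaviorSimParams,
                     coupling: CouplingParams | None = None,
                     loom: LoomParams | None = None):
    """Generate one full session: photometry, trajectory, stimulus train and
    ground truth.

    Behavioral script: OU exploration (with one scripted vigorous movement
    bout), a walk into the threat zone shortly after the exploration period
    (the first in-zone sample is the trigger and disk-1 onset), a stimulus
    arrest, then either a raised-cosine escape ramp to the shelter or, for
    non-escapers, continued wandering that never enters the shelter.  The
    stimulus-evoked transient is injected 0.3-0.6 s (uniform) after disk-1
    onset with an amplitude drawn from the coupling model; escape kinematics
    are drawn from the same model.

    Returns ``(PhotometryRecording, TrackingTrace, StimulusTrain,
    SessionGroundTruth)``.
    """
    loom = loom or LoomParams()
    geom = behav.arena
    rate = behav.tracking_rate
    dt = 1.0 / rate
    rng = np.random.default_rng(behav.seed)

    # --- programmed amplitude and kinematics -------------------------------
    latency_clipped = False
    if coupling is not None:
        amp_z, latency, v_peak, a_peak, esc_amp_z = draw_coupling(coupling, rng)
    else:
        amp_z = 3.0
        latency = behav.escape_latency
        v_peak = behav.escape_peak_velocity
        a_peak = behav.escape_peak_acceleration
        esc_amp_z = 2.0
    floor = max(0.5, behav.min_escape_latency)
    if latency < floor:
        latency = floor
        latency_clipped = True
    v_peak = max(15.0, v_peak)
    a_peak = max(60.0, a_peak)
    approach_delay = rng.uniform(2.0, 8.0)
    stim_jitter = rng.uniform(0.3, 0.6)

    # --- exploration (OU velocity, folded into the non-shelter interior) ---
    tz = geom.threat_zone_size
    box_x = (tz + 1.0, geom.shelter_x - 1.0)
    box_y = (1.0, geom.width - 1.0)
    n_expl = int(round((behav.exploration_duration + approach_delay) * rate))
    vx = _ou_series(rng, n_expl, behav.exploration_speed_scale,
                    behav.exploration_tau, dt)
    vy = _ou_series(rng, n_expl, behav.exploration_speed_scale,
                    behav.exploration_tau, dt)
    # scripted vigorous bout along x (folding preserves its speed profile)
    n_up = max(2, int(round(0.35 * rate)))
    n_hold = max(2, int(round(0.4 * rate)))
    bout_prof = np.concatenate([
        _raised_cos_ramp(n_up, behav.movement_bout_peak, up=True),
        np.full(n_hold, behav.movement_bout_peak),
        _raised_cos_ramp(n_up, behav.movement_bout_peak, up=False)])
    nb = bout_prof.size
    lo_i = int(0.2 * n_expl)
    hi_i = max(lo_i + 1, int(0.7 * n_expl) - nb)
    ib = int(rng.integers(lo_i, hi_i))
    vx[ib:ib + nb] = bout_prof[:min(nb, n_expl - ib)]
    vy[ib:ib + nb] = 0.0
    p0x = 0.5 * (box_x[0] + box_x[1])
    p0y = 0.5 * (box_y[0] + box_y[1])
    ex = _fold(p0x + np.cumsum(vx) * dt, *box_x)
    ey = _fold(p0y + np.cumsum(vy) * dt, *box_y)
    bout_peak_i = ib + n_up + n_hold // 2

    # --- approach: walk to the zone edge, then cross slowly -----------------
    # The crossing happens below the escape-onset speed threshold so that the
    # trigger is not itself mistaken for a movement onset downstream.
    y_mid = 0.5 * min(tz, geom.width)
    edge = np.array([tz + 3.0, y_mid])
    target = np.array([tz - 1.0, y_mid])
    start = np.array([ex[-1], ey[-1]])
    slow_speed = 5.0

    def _walk(p0, p1, speed):
        d = float(np.linalg.norm(p1 - p0))
        n = max(1, int(math.ceil(d / (speed * dt))))
        s = np.minimum(speed * dt * np.arange(1, n + 1), d)
        u = (p1 - p0) / d if d > 0 else np.array([1.0, 0.0])
        return p0[0] + u[0] * s, p0[1] + u[1] * s

    w1x, w1y = _walk(start, edge, behav.approach_speed)
    w2x, w2y = _walk(edge, target, slow_speed)
    ax_ = np.concatenate([w1x, w2x])
    ay_ = np.concatenate([w1y, w2y])
    n_app = ax_.size

    x_parts = [ex, ax_]
    y_parts = [ey, ay_]
    n_sofar = n_expl + n_app

    # trigger: first in-zone sample at/after the exploration period
    in_zone = geom.in_threat_zone(ax_, ay_)
    rel = np.flatnonzero(in_zone)
    if rel.size == 0:
        raise RuntimeError("approach failed to enter the threat zone")
    trigger_i = n_expl + int(rel[0])
    trigger_t = trigger_i * dt

    onset_i = trigger_i + int(round(latency * rate))
    n_dwell = max(0, onset_i - n_sofar)
    onset_i = n_sofar + n_dwell  # realized onset sample (>= programmed)

    # --- stimulus arrest: slow orienting movement inside the zone ----------
    # (arrest is a pause in locomotion, not immobility: speed stays above
    # the freezing ceiling but far below the escape-onset threshold)
    if n_dwell > 0:
        jx = _ou_series(rng, n_dwell, 2.0, 0.5, dt)
        jy = _ou_series(rng, n_dwell, 2.0, 0.5, dt)
        dx_ = _fold(ax_[-1] + np.cumsum(jx) * dt, 1.0, tz - 1.0)
        dy_ = _fold(ay_[-1] + np.cumsum(jy) * dt,
                    1.0, min(tz, geom.width) - 1.0)
        x_parts.append(dx_)
        y_parts.append(dy_)
        n_sofar += n_dwell

    n_total = trigger_i + int(round(behav.post_duration * rate))
    gt_escape_onset = None
    gt_entry = None
    gt_latency = None

    if behav.escapes:
        # --- raised-cosine escape ramp to the shelter ----------------------
        pos = np.array([x_parts[-1][-1], y_parts[-1][-1]])
        goal = np.array([geom.length - 0.5 * geom.shelter_depth, 0.5 * geom.width])
        dist = float(np.linalg.norm(goal - pos))
        u = (goal - pos) / dist
        t1 = min(2.0, max(0.05, 0.5 * math.pi * v_peak / a_peak))
        a_peak = 0.5 * math.pi * v_peak / t1  # realized programmed peak accel
        n1 = max(2, int(round(t1 * rate)))
        ramp = _raised_cos_ramp(n1, v_peak, up=True)
        d_ramp = float(ramp.sum()) * dt
        d_to_entry = (geom.shelter_x - pos[0]) / u[0] + 2.0  # overshoot 2 cm
        n_plateau = max(0, int(math.ceil((d_to_entry - d_ramp) / (v_peak * dt))))
        room = geom.length - 1.0 - (pos[0] + u[0] * (d_ramp + n_plateau * v_peak * dt))
        t2 = max(0.1, min(0.3, 2.0 * max(room, 0.5) / v_peak))
        n2 = max(2, int(round(t2 * rate)))
        speed = np.concatenate([ramp, np.full(n_plateau, v_peak),
                                _raised_cos_ramp(n2, v_peak, up=False)])
        path = np.cumsum(speed) * dt
        exx = np.clip(pos[0] + u[0] * path, None, geom.length - 0.5)
        exy = np.clip(pos[1] + u[1] * path, 0.5, geom.width - 0.5)
        x_parts.append(exx)
        y_parts.append(exy)
        n_sofar += speed.size
        gt_escape_onset = onset_i * dt
        gt_latency = gt_escape_onset - trigger_t
        ent = np.flatnonzero(geom.in_shelter(exx, exy))
        gt_entry = (onset_i + int(ent[0]) + 1) * dt if ent.size else None
        # --- settle in the shelter -----------------------------------------
        n_rest = n_total - n_sofar
        if n_rest > 0:
            jx = _ou_series(rng, n_rest, 0.3, 0.5, dt)
            jy = _ou_series(rng, n_rest, 0.3, 0.5, dt)
            rx = _fold(exx[-1] + np.cumsum(jx) * dt,
                       geom.shelter_x + 0.5, geom.length - 0.5)
            ry = _fold(exy[-1] + np.cumsum(jy) * dt, 0.5, geom.width - 0.5)
            x_parts.append(rx)
            y_parts.append(ry)
            n_sofar += n_rest
    else:
        # wander on, never entering the shelter
        n_rest = n_total - n_sofar
        if n_rest > 0:
            wx = _ou_series(rng, n_rest, 4.0, behav.exploration_tau, dt)
            wy = _ou_series(rng, n_rest, 4.0, behav.exploration_tau, dt)
            rx = _fold(x_parts[-1][-1] + np.cumsum(wx) * dt, 1.0, geom.shelter_x - 1.0)
            ry = _fold(y_parts[-1][-1] + np.cumsum(wy) * dt, *box_y)
            x_parts.append(rx)
            y_parts.append(ry)
            n_sofar += n_rest

    x = np.concatenate(x_parts)[:n_total]
    y = np.concatenate(y_parts)[:n_total]
    time = np.arange(n_total) / rate
    track = TrackingTrace(time=time, x=x, y=y, geometry=geom)

    # --- photometry with the stimulus-locked transient train ---------------
    duration = n_total * dt
    zscale = z_unit_scale(phot)
    times = [trigger_t + stim_jitter]
    amps = [amp_z * zscale]
    if behav.escapes and esc_amp_z > 0 and gt_escape_onset is not None:
        times.append(gt_escape_onset + 0.2)
        amps.append(esc_amp_z * zscale)
    phot_run = replace(phot, duration=duration,
                       transient_times=tuple(times),
                       transient_amplitudes=tuple(amps))
    rec, gt = simulate_photometry(phot_run)
    train = loom_schedule(loom, trigger_t)
    rec.event_times["trigger"] = trigger_t
    for k, onset in enumerate(train.disk_onsets):
        rec.event_times[f"disk{k + 1}"] = onset

    gt.stimulus_amplitude_z = amp_z
    gt.stimulus_transient_time = trigger_t + stim_jitter
    gt.trigger_time = trigger_t
    gt.escapes = behav.escapes
    gt.latency_clipped = latency_clipped
    gt.movement_bout_time = bout_peak_i * dt
    gt.movement_bout_peak = behav.movement_bout_peak
    if behav.escapes:
        gt.escape_onset = gt_escape_onset
        gt.escape_latency = gt_latency
        gt.shelter_entry = gt_entry
        gt.peak_velocity = v_peak
        gt.peak_acceleration = a_peak
    return rec, track, train, gt


def simulate_cohort(n_mice: int, phot: PhotometrySimParams,
                    behav: BehaviorSimParams,
                    coupling: CouplingParams | None = None,
                    loom: LoomParams | None = None,
                    seed: int = 0, n_nonescapers: int = 0):
    """Simulate ``n_mice`` independent sessions with per-mouse seeds derived
    deterministically from the master ``seed``.

    The last ``n_nonescapers`` mice are programmed as non-escapers.  Returns
    ``(sessions, CohortGroundTruth)`` where each session is the 4-tuple from
    :func:`simulate_session`.
    """
    if n_mice < 2:
        raise ValueError("n_mice must be >= 2")
    if not 0 <= n_nonescapers <= n_mice:
        raise ValueError("n_nonescapers must lie in [0, n_mice]")
    state = np.random.SeedSequence(seed).generate_state(2 * n_mice)
    sessions, gts, flags, seeds = [], [], [], []
    for i in range(n_mice):
        ps = int(state[2 * i] % (2 ** 31))
        bs = int(state[2 * i + 1] % (2 ** 31))
        escapes = i < n_mice - n_nonescapers
        sess = simulate_session(
            replace(phot, seed=ps),
            replace(behav, seed=bs, escapes=escapes),
            coupling, loom)
        sessions.append(sess)
        gts.append(sess[3])
        flags.append(escapes)
        seeds.append((ps, bs))
    cohort_gt = CohortGroundTruth(coupling=coupling, sessions=tuple(gts),
                                  escaper_flags=tuple(flags), seeds=tuple(seeds))
    return sessions, cohort_gt
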