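"""Session and cohort orchestration: correct -> z-score -> segment -> align -> test.

Per session the pipeline produces a :class:`SessionResult` (stimulus-evoked
and behavior-aligned transient amplitudes plus escape kinematics); per cohort
it produces a :class:`CohortResult` with the amplitude-kinematics Pearson
correlations (escapers only), the baseline + five-disk repeated-measures
ANOVA with Bonferroni pairwise comparisons, escape- and movement-aligned
paired tests, the escaper/non-escaper comparison, and an optional 2x2
escape-count contingency test for two-arm designs.

Every threshold and window lives in :class:`AnalysisConfig`, a flat sectioned
key = value config that can be written beside the outputs for provenance.
"""
from __future__ import annotations

import configparser
import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import behavior as bv
from . import photometry as ph
from . import stats as st
from .behavior import ArenaGeometry
from .stimulus import LoomParams, loom_schedule

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "SessionResult",
    "CohortResult",
    "analyze_session",
    "analyze_cohort",
    "run_session",
    "run_cohort",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """All analysis thresholds and windows, with the package defaults."""

    # photometry
    lowpass_cutoff: float = 1.5      # Hz; 0 disables the band-limit
    z_epoch_pre: float = 240.0       # s before the trigger
    z_epoch_post: float = 0.0        # s after the trigger (0: baseline-only epoch)
    z_epoch_gap: float = 1.0         # s the epoch ends before the trigger, so the
    # acausal pre-ring of the zero-phase filter cannot leak evoked signal
    # into the normalization window
    response_window: float = 1.0     # s after each disk onset
    peak_prominence: float = 0.5     # z units
    peak_separation: float = 0.25    # s
    align_pre: float = 2.0           # s, event-aligned extraction
    align_post: float = 3.0
    # behavior
    exploration_min: float = 300.0   # s before the trigger rule arms
    smooth_window: float = 0.2       # s position smoothing
    onset_threshold: float = 10.0    # cm/s escape onset
    sustain: float = 0.2             # s above threshold
    escape_window: float = 10.0      # s to reach the shelter
    bout_floor: float = 2.0          # cm/s movement-bout floor
    vigor_threshold: float = 20.0    # cm/s vigorous-bout peak
    merge_gap: float = 0.5           # s bout merging
    freeze_ceiling: float = 1.0      # cm/s
    freeze_min_duration: float = 1.0  # s
    # geometry / stimulus
    geometry: ArenaGeometry = field(default_factory=ArenaGeometry)
    loom: LoomParams = field(default_factory=LoomParams)

    def z_window(self, trigger: float) -> tuple:
        """The z-scoring epoch for a trial triggered at ``trigger`` s."""
        end = trigger - self.z_epoch_gap
        return (end - self.z_epoch_pre, end + self.z_epoch_post)

    _SECTIONS = {
        "photometry": ("lowpass_cutoff", "z_epoch_pre", "z_epoch_post",
                       "z_epoch_gap", "response_window", "peak_prominence",
                       "peak_separation", "align_pre", "align_post"),
        "behavior": ("exploration_min", "smooth_window", "onset_threshold",
                     "sustain", "escape_window", "bout_floor",
                     "vigor_threshold", "merge_gap", "freeze_ceiling",
                     "freeze_min_duration"),
    }

    def to_file(self, path) -> None:
        cp = configparser.ConfigParser()
        for section, keys in self._SECTIONS.items():
            cp[section] = {k: repr(getattr(self, k)) for k in keys}
        cp["arena"] = {k: repr(getattr(self.geometry, k))
                       for k in ("length", "width", "shelter_depth",
                                 "threat_zone_size")}
        cp["stimulus"] = {k: repr(getattr(self.loom, k))
                          for k in ("n_disks", "expand_duration",
                                    "hold_duration", "isi", "final_diameter",
                                    "display_height")}
        with open(path, "w") as fh:
            cp.write(fh)

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        cp = configparser.ConfigParser()
        if not cp.read(path):
            raise FileNotFoundError(path)
        kwargs = {}
        for section, keys in cls._SECTIONS.items():
            for k in keys:
                if cp.has_option(section, k):
                    kwargs[k] = float(cp.get(section, k))
        geo = {}
        for k in ("length", "width", "shelter_depth", "threat_zone_size"):
            if cp.has_option("arena", k):
                geo[k] = float(cp.get("arena", k))
        loom = {}
        if cp.has_section("stimulus"):
            for k in ("expand_duration", "hold_duration", "isi",
                      "final_diameter", "display_height"):
                if cp.has_option("stimulus", k):
                    loom[k] = float(cp.get("stimulus", k))
            if cp.has_option("stimulus", "n_disks"):
                loom["n_disks"] = int(float(cp.get("stimulus", "n_disks")))
        return cls(geometry=ArenaGeometry(**geo), loom=LoomParams(**loom),
                   **kwargs)


@dataclass
class SessionResult:
    """Per-mouse outcome of one threat trial."""

    mouse_id: str
    escaper: bool
    trigger_time: float
    fit_slope: float
    fit_intercept: float
    baseline_amplitude: float
    disk_amplitudes: tuple   # z, one per disk
    disk_latencies: tuple    # s from each disk onset
    escape_latency: float | None = None
    peak_velocity: float | None = None
    peak_acceleration: float | None = None
    shelter_entry: float | None = None
    escape_aligned_amplitude: float | None = None
    movement_aligned_amplitude: float | None = None
    movement_bout_peak: float | None = None
    n_movement_bouts: int = 0
    n_freeze_bouts: int = 0

    def __post_init__(self) -> None:
        if not self.escaper:
            for name in ("escape_latency", "peak_velocity",
                         "peak_acceleration", "shelter_entry",
                         "escape_aligned_amplitude"):
                if getattr(self, name) is not None:
                    raise ValueError(f"{name} must be absent for non-escapers")


@dataclass
class CohortResult:
    sessions: tuple
    n_escapers: int
    correlations: dict                      # metric -> CorrelationResult
    anova: st.RmAnovaResult | None
    escape_vs_baseline: st.TTestResult | None
    movement_vs_baseline: st.TTestResult | None
    escaper_vs_nonescaper: st.TTestResult | None
    contingency: st.ContingencyResult | None


def analyze_session(rec, track, config: AnalysisConfig | None = None,
                    mouse_id: str = "m0") -> SessionResult:
    """Run the full single-session analysis on a recording + trajectory."""
    cfg = config or AnalysisConfig()

    kin = bv.compute_kinematics(track, smooth_window=cfg.smooth_window)
    if "trigger" in rec.event_times:
        trigger = float(rec.event_times["trigger"])
    else:
        trigger = bv.detect_trigger(track, cfg.geometry, cfg.exploration_min)
    train = loom_schedule(cfg.loom, trigger)

    if cfg.lowpass_cutoff > 0:
        rec = ph.lowpass_recording(rec, cfg.lowpass_cutoff)
    corrected = ph.isosbestic_correct(rec)
    z = ph.zscore_epoch(corrected, cfg.z_window(trigger))

    disk_events, baseline = ph.stimulus_response(
        z, train, response_window=cfg.response_window,
        min_prominence=cfg.peak_prominence,
        min_separation=cfg.peak_separation)

    escape = bv.detect_escape(kin, track, train, cfg.geometry,
                              onset_threshold=cfg.onset_threshold,
                              sustain=cfg.sustain,
                              escape_window=cfg.escape_window)
    escaper = bv.classify_escaper(escape)

    esc_amp = None
    if escaper:
        ev, _ = ph.window_response(
            z, (escape.onset, escape.onset + cfg.response_window),
            cfg.peak_prominence, cfg.peak_separation, "escape_onset")
        esc_amp = ev.amplitude

    move_amp = None
    move_peak = None
    bouts = []
    expl_end = max(0.0, trigger - 2.0)
    if expl_end > 1.0:
        bouts = bv.detect_movement_bouts(
            kin, (0.0, expl_end), bout_floor=cfg.bout_floor,
            vigor_threshold=cfg.vigor_threshold, merge_gap=cfg.merge_gap)
    if bouts:
        vig = max(bouts, key=lambda b: b.peak_velocity)
        move_peak = vig.peak_velocity
        if vig.start >= cfg.response_window + 1.0:
            ev, _ = ph.window_response(
                z, (vig.start, vig.start + cfg.response_window),
                cfg.peak_prominence, cfg.peak_separation, "movement_onset")
            move_amp = ev.amplitude

    freezes = bv.detect_freezing(
        kin, track, (trigger, min(float(track.time[-1]),
                                  trigger + cfg.escape_window)),
        cfg.geometry, freeze_ceiling=cfg.freeze_ceiling,
        min_duration=cfg.freeze_min_duration)

    return SessionResult(
        mouse_id=mouse_id,
        escaper=escaper,
        trigger_time=trigger,
        fit_slope=corrected.fit_slope,
        fit_intercept=corrected.fit_intercept,
        baseline_amplitude=baseline,
        disk_amplitudes=tuple(e.amplitude for e in disk_events),
        disk_latencies=tuple(e.latency for e in disk_events),
        escape_latency=escape.latency if escaper else None,
        peak_velocity=escape.peak_velocity if escaper else None,
        peak_acceleration=escape.peak_acceleration if escaper else None,
        shelter_entry=escape.shelter_entry if escaper else None,
        escape_aligned_amplitude=esc_amp,
        movement_aligned_amplitude=move_amp,
        movement_bout_peak=move_peak,
        n_movement_bouts=len(bouts),
        n_freeze_bouts=len(freezes),
    )


def analyze_cohort(results, arm_counts=None, baseline_label: str = "baseline") -> CohortResult:
    """Cohort-level statistics over per-session results.

    Correlations between the first-disk amplitude and each escape kinematic
    are computed on escapers only (>= 3 required, otherwise skipped with a
    warning).  The RM ANOVA runs on the baseline + per-disk amplitude matrix
    across all mice.  ``arm_counts`` — ``((escaped_a, n_a), (escaped_b, n_b))``
    — adds the two-arm escape-count contingency test.
    """
    results = list(results)
    escapers = [r for r in results if r.escaper]
    nonescapers = [r for r in results if not r.escaper]

    correlations = {}
    if len(escapers) >= 3:
        amp = np.array([r.disk_amplitudes[0] for r in escapers])
        for metric, values in (
                ("escape_latency", [r.escape_latency for r in escapers]),
                ("peak_velocity", [r.peak_velocity for r in escapers]),
                ("peak_acceleration", [r.peak_acceleration for r in escapers])):
            correlations[metric] = st.pearson(amp, np.array(values, dtype=float))
    else:
        logger.warning("fewer than 3 escapers; correlation stage skipped")

    anova = None
    if len(results) >= 2:
        mat = np.array([[r.baseline_amplitude, *r.disk_amplitudes]
                        for r in results])
        labels = [baseline_label] + [f"disk{k + 1}"
                                     for k in range(mat.shape[1] - 1)]
        anova = st.one_way_rm_anova(mat, condition_labels=labels,
                                    baseline_index=0,
                                    factor_name="stimulus_number")

    esc_vs_base = None
    if len(escapers) >= 2:
        esc_vs_base = st.t_test(
            np.array([r.escape_aligned_amplitude for r in escapers]),
            np.array([r.baseline_amplitude for r in escapers]), paired=True)

    move = [r for r in results if r.movement_aligned_amplitude is not None]
    move_vs_base = None
    if len(move) >= 2:
        move_vs_base = st.t_test(
            np.array([r.movement_aligned_amplitude for r in move]),
            np.array([r.baseline_amplitude for r in move]), paired=True)

    evn = None
    if len(escapers) >= 2 and len(nonescapers) >= 2:
        evn = st.t_test(
            np.array([r.disk_amplitudes[0] for r in escapers]),
            np.array([r.disk_amplitudes[0] for r in nonescapers]),
            paired=False)

    contingency = None
    if arm_counts is not None:
        (ea, na), (eb, nb) = arm_counts
        contingency = st.chi_squared_gof([[ea, na - ea], [eb, nb - eb]])

    return CohortResult(sessions=tuple(results), n_escapers=len(escapers),
                        correlations=correlations, anova=anova,
                        escape_vs_baseline=esc_vs_base,
                        movement_vs_baseline=move_vs_base,
                        escaper_vs_nonescaper=evn, contingency=contingency)


def run_session(photometry_path, tracking_path, events_path=None,
                config: AnalysisConfig | None = None,
                mouse_id: str | None = None) -> SessionResult:
    """File-based entry point: read the session's delimited-text inputs and
    analyze them.  Stage failures propagate with the offending path."""
    from . import io as _io
    cfg = config or AnalysisConfig()
    events = _io.read_events(events_path) if events_path else {}
    rec = _io.read_photometry(photometry_path, events=events)
    track = _io.read_tracking(tracking_path, geometry=cfg.geometry)
    mid = mouse_id or Path(photometry_path).stem
    logger.info("session %s: %d photometry samples at %.1f Hz, %d tracking samples",
                mid, rec.time.size, rec.sampling_rate, track.time.size)
    return analyze_session(rec, track, cfg, mouse_id=mid)


def run_cohort(session_paths, config: AnalysisConfig | None = None,
               arm_counts=None) -> CohortResult:
    """Analyze a list of ``(photometry, tracking, events-or-None)`` path
    triples as one cohort."""
    results = []
    for i, paths in enumerate(session_paths):
        phot, trk, ev = paths
        results.append(run_session(phot, trk, ev, config=config,
                                   mouse_id=f"m{i}"))
    return analyze_cohort(results, arm_counts=arm_counts)


def session_result_dict(result: SessionResult) -> dict:
    return dataclasses.asdict(result)
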