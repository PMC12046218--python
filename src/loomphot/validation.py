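"""Ground-truth validation experiments for the full pipeline.

Each experiment regenerates synthetic sessions from scratch, runs the
standard analysis, and summarizes how well the programmed quantities are
recovered.  They are used by the acceptance machinery and are convenient
for sanity-checking parameter changes.
"""
from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import photometry as ph
from . import stats as st
from .pipeline import AnalysisConfig, analyze_cohort, analyze_session
from .simulate import (BehaviorSimParams, CouplingParams, PhotometrySimParams,
                       draw_coupling, simulate_cohort, simulate_photometry,
                       simulate_session)
from .stimulus import LoomParams, loom_schedule

__all__ = [
    "subseeds",
    "recovery_experiment",
    "coupling_recovery_experiment",
    "pearson_null_experiment",
    "disk_response_null_experiment",
    "cohort_experiment",
]


def subseeds(seed: int, n: int) -> np.ndarray:
    """Deterministic child seeds (< 2**31) from a master seed."""
    return np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)


def recovery_experiment(n_sessions: int = 50, seed: int = 0,
                        config: AnalysisConfig | None = None) -> dict:
    """Simulate independent escaper sessions at default noise and recover the
    first-disk transient amplitude and escape kinematics.

    Returns injected/recovered amplitude arrays, their Pearson r, and the
    worst-case latency and peak-velocity recovery errors.
    """
    cfg = config or AnalysisConfig()
    phot = PhotometrySimParams()
    behav = BehaviorSimParams()
    coup = CouplingParams()
    seeds = subseeds(seed, 2 * n_sessions)
    inj, rec_amp, lat_err, vel_rel_err = [], [], [], []
    for i in range(n_sessions):
        rec, track, train, gt = simulate_session(
            replace(phot, seed=int(seeds[2 * i])),
            replace(behav, seed=int(seeds[2 * i + 1])), coup)
        res = analyze_session(rec, track, cfg, f"m{i}")
        inj.append(gt.stimulus_amplitude_z)
        rec_amp.append(res.disk_amplitudes[0])
        if res.escaper:
            lat_err.append(abs(res.escape_latency - gt.escape_latency))
            vel_rel_err.append(abs(res.peak_velocity - gt.peak_velocity)
                               / gt.peak_velocity)
    inj = np.array(inj)
    rec_amp = np.array(rec_amp)
    return {
        "injected": inj,
        "recovered": rec_amp,
        "amplitude_r": float(np.corrcoef(inj, rec_amp)[0, 1]),
        "n_escapers": len(lat_err),
        "latency_max_err": float(np.max(lat_err)) if lat_err else float("nan"),
        "velocity_max_rel_err": (float(np.max(vel_rel_err))
                                 if vel_rel_err else float("nan")),
    }


def coupling_recovery_experiment(n_cohorts: int = 100, n_mice: int = 11,
                                 target_r2: float = 0.8, seed: int = 0,
                                 band: float = 0.15,
                                 config: AnalysisConfig | None = None) -> dict:
    """Simulate cohorts with a programmed amplitude-latency R^2 and compare
    the pipeline's estimated R^2 (escapers, Pearson) against it.

    Also reports the coverage of the measurement-free "realized" sample R^2
    computed from the programmed points themselves, which isolates the
    contribution of n-mice sampling noise.
    """
    cfg = config or AnalysisConfig()
    phot = PhotometrySimParams()
    behav = BehaviorSimParams()
    coup = CouplingParams()  # defaults program latency R^2 = 0.8
    seeds = subseeds(seed, n_cohorts)
    est, realized = [], []
    for m in range(n_cohorts):
        sessions, cgt = simulate_cohort(n_mice, phot, behav, coup,
                                        seed=int(seeds[m]))
        results = [analyze_session(rec, trk, cfg, f"m{i}")
                   for i, (rec, trk, tr, g) in enumerate(sessions)]
        cohort = analyze_cohort(results)
        est.append(cohort.correlations["escape_latency"].r_squared)
        realized.append(np.corrcoef(cgt.amplitudes_z, cgt.latencies)[0, 1] ** 2)
    est = np.array(est)
    realized = np.array(realized)
    return {
        "estimated_r2": est,
        "realized_r2": realized,
        "target_r2": target_r2,
        "mean_estimated_r2": float(est.mean()),
        "coverage": float(np.mean(np.abs(est - target_r2) <= band)),
        "realized_coverage": float(np.mean(np.abs(realized - target_r2) <= band)),
    }


def pearson_null_experiment(n_runs: int = 2000, n: int = 11,
                            seed: int = 0, alpha: float = 0.05) -> float:
    """Rejection rate of the amplitude-kinematics correlation test when the
    programmed coupling slopes are zero (draws from the generator's coupling
    model; amplitudes and latencies are then independent)."""
    null = CouplingParams(latency_slope=0.0, velocity_slope=0.0,
                          acceleration_slope=0.0)
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_runs):
        draws = [draw_coupling(null, rng) for _ in range(n)]
        amp = np.array([d[0] for d in draws])
        lat = np.array([d[1] for d in draws])
        if st.pearson(amp, lat).p < alpha:
            rejections += 1
    return rejections / n_runs


def disk_response_null_experiment(n_runs: int = 2000, n_mice: int = 16,
                                  seed: int = 0, alpha: float = 0.05,
                                  duration: float = 30.0,
                                  trigger: float = 12.0,
                                  config: AnalysisConfig | None = None) -> float:
    """Rejection rate of the disk-1-vs-baseline paired t test on recordings
    with no injected stimulus transient (spontaneous events and noise only)."""
    cfg = config or AnalysisConfig()
    phot = PhotometrySimParams(duration=duration)
    loom = cfg.loom
    train = loom_schedule(loom, trigger)
    seeds = subseeds(seed, n_runs * n_mice)
    rejections = 0
    k = 0
    for _ in range(n_runs):
        disk1, base = [], []
        for _m in range(n_mice):
            rec, _gt = simulate_photometry(replace(phot, seed=int(seeds[k])))
            k += 1
            if cfg.lowpass_cutoff > 0:
                rec = ph.lowpass_recording(rec, cfg.lowpass_cutoff)
            trace = ph.isosbestic_correct(rec)
            z = ph.zscore_epoch(trace, cfg.z_window(trigger))
            events, baseline = ph.stimulus_response(
                z, train, response_window=cfg.response_window,
                min_prominence=cfg.peak_prominence,
                min_separation=cfg.peak_separation)
            disk1.append(events[0].amplitude)
            base.append(baseline)
        if st.t_test(np.array(disk1), np.array(base), paired=True).p < alpha:
            rejections += 1
    return rejections / n_runs


def cohort_experiment(n_mice: int = 16, n_nonescapers: int = 5, seed: int = 0,
                      config: AnalysisConfig | None = None):
    """One full cohort at the assay's size (default 16 mice, 11 escapers),
    analyzed end to end.  Returns ``(CohortResult, list_of_ground_truths)``."""
    cfg = config or AnalysisConfig()
    sessions, cgt = simulate_cohort(
        n_mice, PhotometrySimParams(), BehaviorSimParams(), CouplingParams(),
        seed=seed, n_nonescapers=n_nonescapers)
    results = [analyze_session(rec, trk, cfg, f"m{i}")
               for i, (rec, trk, tr, g) in enumerate(sessions)]
    return analyze_cohort(results, arm_counts=((8, 10), (1, 8))), cgt
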