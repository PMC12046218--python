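"""Looming-disk stimulus protocol.

An overhead display presents a train of expanding dark (or contrast-inverted)
disks whenever the mouse enters the threat zone.  This module owns the
schedule arithmetic (trigger-locked onsets/offsets), the disk expansion
profile, and the viewing geometry that converts disk size into visual angle.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "LoomParams",
    "StimulusTrain",
    "loom_schedule",
    "disk_diameter",
    "visual_angle",
    "disk_index_at",
]

_CONTRASTS = ("dark", "inverted")


@dataclass(frozen=True)
class LoomParams:
    """Parameters of the looming-disk protocol.

    Defaults reproduce the standard assay: five disks, each expanding from
    0 to 19.5 cm over 0.25 s and holding at full size for 0.25 s, separated
    by a 0.5 s inter-stimulus interval (offset-to-onset), displayed 40.5 cm
    above the arena floor.
    """

    n_disks: int = 5
    expand_duration: float = 0.25  # s
    hold_duration: float = 0.25    # s
    isi: float = 0.5               # s, offset-to-onset gap
    final_diameter: float = 19.5   # cm
    display_height: float = 40.5   # cm above arena floor
    contrast: str = "dark"
    isi_mode: str = "offset_to_onset"  # or "onset_to_onset"

    def __post_init__(self) -> None:
        if self.n_disks < 1:
            raise ValueError("n_disks must be >= 1")
        for name in ("expand_duration", "hold_duration", "isi",
                     "final_diameter", "display_height"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v}")
        if self.contrast not in _CONTRASTS:
            raise ValueError(f"contrast must be one of {_CONTRASTS}")
        if self.isi_mode not in ("offset_to_onset", "onset_to_onset"):
            raise ValueError("isi_mode must be 'offset_to_onset' or 'onset_to_onset'")
        if self.isi_mode == "onset_to_onset" and self.isi < self.stimulus_duration:
            raise ValueError("onset-to-onset ISI shorter than the stimulus itself")

    @property
    def stimulus_duration(self) -> float:
        """Duration of a single disk presentation (expand + hold), s."""
        return self.expand_duration + self.hold_duration

    @property
    def period(self) -> float:
        """Onset-to-onset interval between consecutive disks, s."""
        if self.isi_mode == "offset_to_onset":
            return self.stimulus_duration + self.isi
        return self.isi


@dataclass(frozen=True)
class StimulusTrain:
    """Concrete schedule of one triggered disk train (all times in s)."""

    trigger_time: float
    disk_onsets: tuple
    disk_offsets: tuple
    contrast: str = "dark"

    def __post_init__(self) -> None:
        onsets = tuple(float(t) for t in self.disk_onsets)
        offsets = tuple(float(t) for t in self.disk_offsets)
        object.__setattr__(self, "disk_onsets", onsets)
        object.__setattr__(self, "disk_offsets", offsets)
        if len(onsets) != len(offsets) or not onsets:
            raise ValueError("disk_onsets and disk_offsets must be equal-length, non-empty")
        if any(b <= a for a, b in zip(onsets[:-1], onsets[1:])):
            raise ValueError("disk onsets must be strictly increasing")
        durs = [off - on for on, off in zip(onsets, offsets)]
        if any(d <= 0 for d in durs):
            raise ValueError("each disk offset must follow its onset")
        if any(abs(d - durs[0]) > 1e-9 for d in durs):
            raise ValueError("all disks must share the same duration")

    @property
    def n_disks(self) -> int:
        return len(self.disk_onsets)

    @property
    def end_time(self) -> float:
        return self.disk_offsets[-1]


def loom_schedule(params: LoomParams, trigger_time: float) -> StimulusTrain:
    """Build the disk train triggered at ``trigger_time``.

    Onset of disk k is ``trigger_time + k * period`` where the period is the
    onset-to-onset interval implied by the ISI convention in ``params``.
    """
    if not (math.isfinite(trigger_time) and trigger_time >= 0):
        raise ValueError("trigger_time must be finite and >= 0")
    onsets = tuple(trigger_time + k * params.period for k in range(params.n_disks))
    offsets = tuple(t + params.stimulus_duration for t in onsets)
    return StimulusTrain(trigger_time, onsets, offsets, contrast=params.contrast)


def disk_diameter(t_rel: float, params: LoomParams) -> float:
    """Disk diameter (cm) at time ``t_rel`` s after disk onset.

    Linear expansion from 0 to ``final_diameter`` over ``expand_duration``,
    then constant during the hold.  ``t_rel`` outside [0, expand + hold]
    raises ValueError.
    """
    if not (0.0 <= t_rel <= params.stimulus_duration):
        raise ValueError(
            f"t_rel={t_rel} outside the stimulus [0, {params.stimulus_duration}]")
    if t_rel < params.expand_duration:
        return params.final_diameter * t_rel / params.expand_duration
    return params.final_diameter


def visual_angle(diameter: float, viewing_distance: float) -> float:
    """Full visual angle (degrees) subtended by a disk of ``diameter`` cm
    viewed from ``viewing_distance`` cm.

    Uses the exact subtense 2*atan(d / 2D); for the default geometry
    (19.5 cm disk, 40.5 cm display height) this is 27.1 degrees.
    """
    if diameter < 0:
        raise ValueError("diameter must be >= 0")
    if not viewing_distance > 0:
        raise ValueError("viewing_distance must be > 0")
    return math.degrees(2.0 * math.atan(diameter / (2.0 * viewing_distance)))


def disk_index_at(train: StimulusTrain, t: float) -> int | None:
    """0-based index of the disk on screen at time ``t``, or None if no disk
    is displayed (between disks / outside the train)."""
    for k, (on, off) in enumerate(zip(train.disk_onsets, train.disk_offsets)):
        if on <= t <= off:
            return k
    return None
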