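"""Delimited-text readers and writers for the assay's file formats.

Formats:

* photometry CSV with header ``time,f465,f405`` (s, a.u., a.u.);
* tracking CSV with header ``time,x,y`` (s, cm, cm, arena frame);
* event timestamps as two-column text ``label,time_s``;
* corrected traces as CSV preceded by a ``# key = value`` metadata block
  (fit coefficients, epoch window);
* session/cohort results as tidy long-format CSV (one row per measure);
* ground-truth sidecars as JSON.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import ArenaGeometry, TrackingTrace
from .photometry import CorrectedTrace, PhotometryRecording

__all__ = [
    "ParseError",
    "read_photometry",
    "write_photometry",
    "read_tracking",
    "write_tracking",
    "read_events",
    "write_events",
    "read_corrected_trace",
    "write_corrected_trace",
    "write_ground_truth",
    "read_ground_truth",
    "session_results_frame",
    "write_session_results",
]


class ParseError(ValueError):
    """Malformed input file; the message names the file and line."""


def _read_table(path, columns) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: line 1: missing column(s) {missing}")
    sub = df[list(columns)]
    bad = sub.isna().any(axis=1)
    if bad.any():
        # +2: header line plus 1-based indexing
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ParseError(f"{path}: line {line}: missing or non-numeric value")
    return sub


def read_photometry(path, events=None) -> PhotometryRecording:
    """Read a ``time,f465,f405`` CSV; sampling rate is inferred from the grid."""
    df = _read_table(path, ("time", "f465", "f405"))
    t = df["time"].to_numpy(dtype=float)
    if t.size < 2:
        raise ParseError(f"{path}: needs at least 2 samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    return PhotometryRecording(time=t, f465=df["f465"].to_numpy(dtype=float),
                               f405=df["f405"].to_numpy(dtype=float),
                               sampling_rate=fs, event_times=dict(events or {}))


def write_photometry(path, rec: PhotometryRecording) -> None:
    pd.DataFrame({"time": rec.time, "f465": rec.f465, "f405": rec.f405}).to_csv(
        path, index=False, float_format="%.6f")


def read_tracking(path, geometry: ArenaGeometry | None = None) -> TrackingTrace:
    df = _read_table(path, ("time", "x", "y"))
    return TrackingTrace(time=df["time"].to_numpy(dtype=float),
                         x=df["x"].to_numpy(dtype=float),
                         y=df["y"].to_numpy(dtype=float), geometry=geometry)


def write_tracking(path, track: TrackingTrace) -> None:
    pd.DataFrame({"time": track.time, "x": track.x, "y": track.y}).to_csv(
        path, index=False, float_format="%.4f")


def read_events(path) -> dict:
    """Read a labelled timestamp file (``label,time_s`` or whitespace-separated)."""
    path = Path(path)
    out = {}
    for i, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p for p in line.replace(",", " ").split() if p]
        if len(parts) != 2:
            raise ParseError(f"{path}: line {i}: expected 'label time_s'")
        if parts[0] == "label":  # optional header
            continue
        try:
            out[parts[0]] = float(parts[1])
        except ValueError as exc:
            raise ParseError(f"{path}: line {i}: non-numeric time {parts[1]!r}") from exc
    return out


def write_events(path, events: dict) -> None:
    lines = ["label,time_s"]
    lines += [f"{k},{v:.6f}" for k, v in sorted(events.items(), key=lambda kv: kv[1])]
    Path(path).write_text("\n".join(lines) + "\n")


def write_corrected_trace(path, trace: CorrectedTrace) -> None:
    """CSV with a ``# key = value`` metadata header block."""
    meta = [
        f"# fit_slope = {trace.fit_slope!r}",
        f"# fit_intercept = {trace.fit_intercept!r}",
        f"# sampling_rate = {trace.sampling_rate!r}",
    ]
    if trace.epoch_window is not None:
        meta.append(f"# epoch_window = {trace.epoch_window[0]!r} {trace.epoch_window[1]!r}")
    cols = {"time": trace.time, "dff": trace.dff}
    if trace.z is not None:
        cols["z"] = trace.z
    body = pd.DataFrame(cols).to_csv(index=False, float_format="%.8g")
    Path(path).write_text("\n".join(meta) + "\n" + body)


def read_corrected_trace(path) -> CorrectedTrace:
    path = Path(path)
    meta = {}
    for raw in path.read_text().splitlines():
        if not raw.startswith("#"):
            break
        key, _, val = raw.lstrip("# ").partition("=")
        meta[key.strip()] = val.strip()
    df = _read_table(path, ("time", "dff"))
    z = None
    full = pd.read_csv(path, comment="#")
    if "z" in full.columns:
        z = full["z"].to_numpy(dtype=float)
    window = None
    if "epoch_window" in meta:
        a, b = meta["epoch_window"].split()
        window = (float(a), float(b))
    return CorrectedTrace(
        time=df["time"].to_numpy(dtype=float),
        dff=df["dff"].to_numpy(dtype=float),
        fit_slope=float(meta.get("fit_slope", "nan")),
        fit_intercept=float(meta.get("fit_intercept", "nan")),
        sampling_rate=float(meta["sampling_rate"]),
        z=z, epoch_window=window)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def write_ground_truth(path, gt) -> None:
    Path(path).write_text(json.dumps(_jsonable(gt), indent=1) + "\n")


def read_ground_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def session_results_frame(results) -> pd.DataFrame:
    """Tidy long format: one row per (mouse, measure)."""
    rows = []
    for r in results:
        d = dataclasses.asdict(r)
        mouse = d.pop("mouse_id")
        for key, val in d.items():
            if isinstance(val, (list, tuple)):
                for k, v in enumerate(val):
                    rows.append({"mouse_id": mouse, "measure": f"{key}_{k + 1}",
                                 "value": v})
            else:
                rows.append({"mouse_id": mouse, "measure": key, "value": val})
    return pd.DataFrame(rows)


def write_session_results(path, results) -> None:
    session_results_frame(results).to_csv(path, index=False)
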