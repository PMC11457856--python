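"""Readers/writers for waveform CSVs, EIT frame directories, and scenario
configuration files.

Waveform CSV format: columns ``time_s, paw_cmH2O, flow_lpm, vol_ml`` with a
header row, UTF-8, one file per subject; an optional JSON sidecar
(``<name>.json``) carries subject metadata, generating settings and seeds.
EIT frames are a directory of one CSV per frame (row 0 most ventral) plus
``lung_mask.csv`` and ``meta.json``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import Scenario
from .core import EITFrameSeries, WaveformRecording

__all__ = ["write_waveform_csv", "read_waveform_csv", "write_eit_frames",
           "read_eit_frames", "load_scenario", "dump_json"]

WAVEFORM_COLUMNS = ("time_s", "paw_cmH2O", "flow_lpm", "vol_ml")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def dump_json(obj, path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n",
        encoding="utf-8")


def write_waveform_csv(recording: WaveformRecording, path,
                       sidecar: bool = True) -> Path:
    """Write a recording; round-trips through :func:`read_waveform_csv`
    to < 1e-9."""
    path = Path(path)
    df = pd.DataFrame({
        "time_s": recording.time, "paw_cmH2O": recording.pressure,
        "flow_lpm": recording.flow, "vol_ml": recording.volume,
    })
    df.to_csv(path, index=False, float_format="%.12g")
    if sidecar:
        dump_json({
            "subject_id": recording.subject_id, "weight_kg": recording.weight,
            "group_label": recording.group_label,
            "sample_rate_hz": recording.sample_rate, "meta": recording.meta,
        }, path.with_suffix(path.suffix + ".json"))
    return path


def read_waveform_csv(path) -> WaveformRecording:
    """Read a waveform CSV (+ sidecar when present).

    Raises with the offending column name on malformed headers and with the
    maximum gap on non-uniform timestamps.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in WAVEFORM_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing required column {col!r} "
                             f"(header has {list(df.columns)})")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path.name}: needs at least 2 samples")
    dt = np.diff(t)
    dt_med = float(np.median(dt))
    worst = int(np.argmax(np.abs(dt - dt_med)))
    if abs(dt[worst] - dt_med) > 1e-6 * dt_med + 1e-12:
        raise ValueError(
            f"{path.name}: non-uniform timestamps; max gap {dt.max():.6g} s "
            f"vs median step {dt_med:.6g} s (line {worst + 2})")
    meta, subject_id, weight, group = {}, path.stem, 1.0, ""
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        side = json.loads(sidecar.read_text(encoding="utf-8"))
        meta = side.get("meta", {})
        subject_id = side.get("subject_id", subject_id)
        weight = side.get("weight_kg", weight)
        group = side.get("group_label", group)
    return WaveformRecording(
        time=t, pressure=df["paw_cmH2O"].to_numpy(dtype=float),
        flow=df["flow_lpm"].to_numpy(dtype=float),
        volume=df["vol_ml"].to_numpy(dtype=float),
        sample_rate=1.0 / dt_med, subject_id=subject_id, weight=weight,
        group_label=group, meta=meta)


def write_eit_frames(series: EITFrameSeries, dirpath) -> Path:
    """One CSV per frame (``frame_00000.csv`` ...), ``lung_mask.csv``, and
    ``meta.json`` with times and frame rate."""
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(series.frames):
        np.savetxt(d / f"frame_{i:05d}.csv", frame, delimiter=",", fmt="%.10g")
    np.savetxt(d / "lung_mask.csv", series.lung_mask.astype(int),
               delimiter=",", fmt="%d")
    dump_json({"times_s": series.times, "frame_rate_hz": series.frame_rate,
               "meta": series.meta}, d / "meta.json")
    return d


def read_eit_frames(dirpath) -> EITFrameSeries:
    d = Path(dirpath)
    meta = json.loads((d / "meta.json").read_text(encoding="utf-8"))
    frame_files = sorted(d.glob("frame_*.csv"))
    if not frame_files:
        raise ValueError(f"{d}: no frame CSVs found")
    frames = np.stack([np.loadtxt(f, delimiter=",", ndmin=2) for f in frame_files])
    mask = np.loadtxt(d / "lung_mask.csv", delimiter=",", ndmin=2).astype(bool)
    return EITFrameSeries(frames=frames, times=np.asarray(meta["times_s"]),
                          frame_rate=meta["frame_rate_hz"], lung_mask=mask,
                          meta=meta.get("meta", {}))


def load_scenario(path) -> Scenario:
    """Load a scenario from YAML/JSON; unknown keys raise to catch typos."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    valid = {f.name for f in dataclasses.fields(Scenario)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    if "noise_sd" in raw:
        raw["noise_sd"] = tuple(raw["noise_sd"])
    return Scenario(**raw)
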