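"""CSV/JSON interchange for trajectories, traces, ACFs and reports.

The native trajectory dialect is the long-format table written by
``TrajectorySet.to_frame``: one row per localization with columns
``track_id, frame, t, x, y`` (µm, seconds) and an optional ``truth_label``.
A TrackMate-style export (``TRACK_ID, FRAME, POSITION_X, POSITION_Y`` headers,
possibly followed by the extra non-numeric header rows TrackMate emits) is
read-only; positions are taken as µm unless ``position_units='pixel'``, in
which case they are scaled by the camera pixel size (0.065 µm at ×100 by
default).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._tracks import TrajectorySet
from .fcs import ACFCurve
from .simulate import IntensityTrace

__all__ = [
    "read_tracks",
    "write_tracks",
    "read_trace",
    "write_trace",
    "read_acf",
    "write_acf",
    "load_simulation_config",
    "write_report",
]

DEFAULT_PIXEL_SIZE = 0.065  # µm per camera pixel at ×100

_TRACKMATE_COLUMNS = {
    "TRACK_ID": "track_id",
    "FRAME": "frame",
    "POSITION_X": "x",
    "POSITION_Y": "y",
}


def read_tracks(
    path,
    dialect: str = "native",
    frame_interval: float = 0.01,
    position_units: str = "um",
    pixel_size: float = DEFAULT_PIXEL_SIZE,
) -> TrajectorySet:
    """Read a trajectory CSV in the native or TrackMate-style dialect.

    Frames must be strictly increasing within each track; duplicated frame
    indices or NaN positions raise with the offending track identified.
    """
    df = pd.read_csv(path)
    if dialect == "trackmate":
        missing = [c for c in _TRACKMATE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"TrackMate export missing columns: {missing}")
        df = df[list(_TRACKMATE_COLUMNS)].rename(columns=_TRACKMATE_COLUMNS)
        # TrackMate exports carry extra header rows (labels/units); drop non-numeric rows
        df = df.apply(pd.to_numeric, errors="coerce").dropna(how="all")
        if position_units == "pixel":
            df[["x", "y"]] *= pixel_size
        elif position_units != "um":
            raise ValueError("position_units must be 'um' or 'pixel'")
    elif dialect == "native":
        missing = [c for c in ("track_id", "frame", "x", "y") if c not in df.columns]
        if missing:
            raise ValueError(f"native trajectory CSV missing columns: {missing}")
    else:
        raise ValueError("dialect must be 'native' or 'trackmate'")
    if df[["x", "y"]].isna().any().any():
        bad = df.index[df[["x", "y"]].isna().any(axis=1)][0]
        raise ValueError(f"NaN position at row {bad}")
    for tid, grp in df.groupby("track_id"):
        frames = grp["frame"].to_numpy()
        if np.any(np.diff(frames) <= 0):
            row = grp.index[np.argmax(np.diff(frames) <= 0) + 1]
            raise ValueError(f"track {tid}: non-monotone or duplicated frame index at row {row}")
    return TrajectorySet.from_frame(df, frame_interval=frame_interval)


def write_tracks(tracks: TrajectorySet, path) -> None:
    tracks.to_frame().to_csv(path, index=False)


def write_trace(trace: IntensityTrace, path) -> None:
    pd.DataFrame({"t": trace.times, "counts": trace.counts}).to_csv(path, index=False)


def read_trace(path) -> IntensityTrace:
    df = pd.read_csv(path)
    if not {"t", "counts"}.issubset(df.columns):
        raise ValueError("trace CSV needs columns t, counts")
    t = df["t"].to_numpy()
    if t.size < 2:
        raise ValueError("trace needs at least two bins")
    return IntensityTrace(bin_width=float(t[1] - t[0]), counts=df["counts"].to_numpy(dtype=np.int64))


def write_acf(acf: ACFCurve, path) -> None:
    out = pd.DataFrame({"lag_s": acf.lags, "g": acf.g})
    if acf.uncertainties is not None:
        out["sigma"] = acf.uncertainties
    out.to_csv(path, index=False)


def read_acf(path, duration: float | None = None) -> ACFCurve:
    df = pd.read_csv(path)
    if not {"lag_s", "g"}.issubset(df.columns):
        raise ValueError("ACF CSV needs columns lag_s, g")
    sig = df["sigma"].to_numpy() if "sigma" in df.columns else None
    return ACFCurve(lags=df["lag_s"].to_numpy(), g=df["g"].to_numpy(), uncertainties=sig, duration=duration)


def load_simulation_config(path) -> "SimulationConfig":
    """Build a :class:`~sptfcs.simulate.SimulationConfig` from a YAML or JSON file.

    Unknown keys raise rather than being silently ignored.
    """
    import yaml

    from .simulate import SimulationConfig

    raw = Path(path).read_text()
    data = yaml.safe_load(raw)  # YAML is a superset of JSON
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping of fields")
    valid = set(SimulationConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    config = SimulationConfig(**data)
    config.validate()
    return config


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_report(report: dict, path, config: dict | None = None, seed: int | None = None) -> None:
    """Write a JSON report stamped with package version, seed and config hash."""
    payload = dict(report)
    payload["_provenance"] = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": _config_hash(config or {}),
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
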