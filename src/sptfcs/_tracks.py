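"""Trajectory containers shared by the simulators and the MSD analysis."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class Trajectory:
    """One tracked particle: time-ordered 2D localizations at a fixed frame interval.

    Positions are in µm; ``frames`` are 0-based integer frame indices and must be
    strictly increasing. ``label`` carries ground-truth provenance for simulated
    tracks (e.g. the source condition of a mixture) and is ``None`` for real data.
    """

    track_id: int
    frames: np.ndarray
    xy: np.ndarray
    frame_interval: float
    label: str | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.frames.ndim != 1 or self.xy.shape != (self.frames.size, 2):
            raise ValueError("frames must be 1D and xy must be (n, 2)")
        if self.frames.size < 2:
            raise ValueError("a trajectory needs at least 2 localizations")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError(f"track {self.track_id}: frame indices not strictly increasing")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError(f"track {self.track_id}: non-finite positions")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    def __len__(self) -> int:
        return self.frames.size

    @property
    def times(self) -> np.ndarray:
        return self.frames * self.frame_interval


@dataclass
class TrajectorySet:
    """A collection of trajectories sharing one frame interval."""

    tracks: list[Trajectory] = field(default_factory=list)
    frame_interval: float = 0.01

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    def labels(self) -> list[str | None]:
        return [t.label for t in self.tracks]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per localization, sorted by (track_id, frame)."""
        parts = []
        for t in self.tracks:
            df = pd.DataFrame(
                {
                    "track_id": t.track_id,
                    "frame": t.frames,
                    "t": t.times,
                    "x": t.xy[:, 0],
                    "y": t.xy[:, 1],
                }
            )
            if t.label is not None:
                df["truth_label"] = t.label
            parts.append(df)
        if not parts:
            return pd.DataFrame(columns=["track_id", "frame", "t", "x", "y"])
        out = pd.concat(parts, ignore_index=True)
        return out.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, frame_interval: float) -> "TrajectorySet":
        tracks = []
        has_label = "truth_label" in df.columns
        for tid, grp in df.groupby("track_id", sort=True):
            grp = grp.sort_values("frame", kind="stable")
            label = grp["truth_label"].iloc[0] if has_label else None
            tracks.append(
                Trajectory(
                    track_id=int(tid),
                    frames=grp["frame"].to_numpy(),
                    xy=grp[["x", "y"]].to_numpy(),
                    frame_interval=frame_interval,
                    label=None if label is None or (isinstance(label, float) and np.isnan(label)) else str(label),
                )
            )
        return cls(tracks=tracks, frame_interval=frame_interval)
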