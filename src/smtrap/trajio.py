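"""Trajectory data model and CSV I/O.

Single-particle-tracking data enter the pipeline as tidy tables with one
localization per row (cell, channel, trajectory, frame, x/y in micrometres,
spot intensity), as produced by any SPT tracker after spot detection and
linking.  This module turns those tables into :class:`Trajectory` /
:class:`TrackSet` objects shared by every downstream analysis stage, and
centralizes the unit conventions: coordinates are stored in μm, confinement
zone sizes are reported in nm, frames are 0-based, and the frame interval
``dt`` defaults to 1/30 s (video rate, 33.3 ms).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

NM_PER_UM = 1000.0
#: video-rate frame interval in seconds (33.3 ms)
DEFAULT_DT = 1.0 / 30.0

#: required columns of a trajectory CSV, in canonical order
TRACK_COLUMNS = (
    "cell_id",
    "channel",
    "trajectory_id",
    "frame",
    "x_um",
    "y_um",
    "intensity",
)


class TrackFormatError(ValueError):
    """Raised when a trajectory table violates the documented CSV schema."""


@dataclass(frozen=True)
class ChannelModel:
    """Optical properties of one imaging channel.

    Parameters
    ----------
    sigma_axis : float
        Per-axis localization precision in nm (SD of repeated position
        estimates of a stationary emitter).
    bleach_lifetime : float
        Mean time in seconds before single-step photobleaching, from a
        single-exponential fit of on-times of immobilized probes.
    """

    sigma_axis: float
    bleach_lifetime: float

    def __post_init__(self) -> None:
        if not self.sigma_axis > 0:
            raise ValueError(f"sigma_axis must be > 0, got {self.sigma_axis}")
        if not self.bleach_lifetime > 0:
            raise ValueError(
                f"bleach_lifetime must be > 0, got {self.bleach_lifetime}"
            )


# channel models measured for the green (tdStayGold-like) and red (TMR-like)
# probes at video rate
GREEN = ChannelModel(sigma_axis=14.0, bleach_lifetime=10.4)
RED = ChannelModel(sigma_axis=18.7, bleach_lifetime=8.1)


@dataclass
class Trajectory:
    """One molecule's ordered 2-D localizations at a fixed frame interval.

    Frames must be strictly consecutive integers (gap handling happens at
    read time, see :func:`read_tracks`) and at least two positions are
    required so that at least one displacement exists.
    """

    cell_id: str
    channel: str
    trajectory_id: str
    frames: np.ndarray
    xy: np.ndarray
    dt: float = DEFAULT_DT
    intensity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must have shape (N, 2)")
        n = len(self.frames)
        if n != len(self.xy):
            raise ValueError("frames and xy lengths differ")
        if n < 2:
            raise ValueError("a trajectory needs at least 2 localizations")
        if np.any(np.diff(self.frames) != 1):
            raise ValueError("frames must be strictly consecutive")
        if self.frames[0] < 0:
            raise ValueError("frame indices must be >= 0")
        if not np.all(np.isfinite(self.xy)):
            raise ValueError("positions must be finite")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if self.intensity is None:
            self.intensity = np.zeros(n)
        else:
            self.intensity = np.asarray(self.intensity, dtype=float)
            if len(self.intensity) != n:
                raise ValueError("intensity length differs from frames")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        """Tracked time in seconds, counted as frames × dt."""
        return self.n_frames * self.dt

    def __len__(self) -> int:
        return self.n_frames


@dataclass
class TrackSet:
    """A collection of trajectories sharing one frame interval.

    Trajectories are grouped by cell and channel for the per-cell summary
    statistics; ``channel_models`` carries the localization precision and
    bleach lifetime used by precision-corrected estimators.
    """

    trajectories: list[Trajectory] = field(default_factory=list)
    dt: float = DEFAULT_DT
    channel_models: dict[str, ChannelModel] = field(default_factory=dict)
    condition: str = ""
    time_point: str = ""

    def __post_init__(self) -> None:
        for t in self.trajectories:
            if not np.isclose(t.dt, self.dt):
                raise ValueError("all member trajectories must share dt")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.trajectories)

    @property
    def cells(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.trajectories:
            seen.setdefault(t.cell_id)
        return list(seen)

    @property
    def channels(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.trajectories:
            seen.setdefault(t.channel)
        return list(seen)

    def by_cell(self) -> dict[str, list[Trajectory]]:
        out: dict[str, list[Trajectory]] = {}
        for t in self.trajectories:
            out.setdefault(t.cell_id, []).append(t)
        return out

    def sigma_axis(self, channel: str, default: float | None = None) -> float:
        """Per-axis localization precision (nm) for ``channel``."""
        if channel in self.channel_models:
            return self.channel_models[channel].sigma_axis
        if default is not None:
            return default
        raise KeyError(f"no ChannelModel for channel {channel!r}")

    def to_frame(self) -> pd.DataFrame:
        """Flatten to the canonical one-row-per-localization table."""
        parts = []
        for t in self.trajectories:
            parts.append(
                pd.DataFrame(
                    {
                        "cell_id": t.cell_id,
                        "channel": t.channel,
                        "trajectory_id": t.trajectory_id,
                        "frame": t.frames,
                        "x_um": t.xy[:, 0],
                        "y_um": t.xy[:, 1],
                        "intensity": t.intensity,
                    }
                )
            )
        if not parts:
            return pd.DataFrame(columns=list(TRACK_COLUMNS))
        return pd.concat(parts, ignore_index=True)


def _split_consecutive(frames: np.ndarray) -> list[np.ndarray]:
    """Index runs of consecutive frames (gap-splitting rule)."""
    breaks = np.flatnonzero(np.diff(frames) != 1) + 1
    return np.split(np.arange(len(frames)), breaks)


def tracks_from_frame(
    df: pd.DataFrame,
    dt: float = DEFAULT_DT,
    channel_models: Mapping[str, ChannelModel] | None = None,
    condition: str = "",
    time_point: str = "",
) -> TrackSet:
    """Build a TrackSet from a localization table already in memory.

    Rows are grouped by (cell, channel, trajectory) and sorted by frame.
    Frame gaps split a trajectory into separate pieces with suffixed ids
    (``id.1``, ``id.2``, ...) because the confinement detectors assume
    consecutive frames; single-frame fragments are dropped (they carry no
    displacement information).
    """
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(f"missing required column(s): {', '.join(missing)}")
    bad = ~np.isfinite(df["x_um"].to_numpy(float)) | ~np.isfinite(
        df["y_um"].to_numpy(float)
    )
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise TrackFormatError(f"non-finite coordinate at data row {row}")
    dup = df.duplicated(subset=["cell_id", "channel", "trajectory_id", "frame"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise TrackFormatError(
            f"duplicate (cell, channel, trajectory, frame) key at data row {row}"
        )

    trajectories: list[Trajectory] = []
    for (cell, channel, tid), g in df.groupby(
        ["cell_id", "channel", "trajectory_id"], sort=True
    ):
        g = g.sort_values("frame")
        frames = g["frame"].to_numpy(np.int64)
        xy = g[["x_um", "y_um"]].to_numpy(float)
        inten = g["intensity"].to_numpy(float)
        pieces = _split_consecutive(frames)
        for k, idx in enumerate(pieces):
            if len(idx) < 2:
                continue
            piece_id = str(tid) if len(pieces) == 1 else f"{tid}.{k}"
            trajectories.append(
                Trajectory(
                    cell_id=str(cell),
                    channel=str(channel),
                    trajectory_id=piece_id,
                    frames=frames[idx],
                    xy=xy[idx],
                    dt=dt,
                    intensity=inten[idx],
                )
            )
    return TrackSet(
        trajectories=trajectories,
        dt=dt,
        channel_models=dict(channel_models or {}),
        condition=condition,
        time_point=time_point,
    )


def read_tracks(
    path: str | Path | io.TextIOBase,
    dt: float = DEFAULT_DT,
    channel_models: Mapping[str, ChannelModel] | None = None,
    condition: str = "",
    time_point: str = "",
) -> TrackSet:
    """Read a trajectory CSV (see :data:`TRACK_COLUMNS`) into a TrackSet."""
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise TrackFormatError(f"cannot parse trajectory CSV: {exc}") from exc
    return tracks_from_frame(
        df, dt=dt, channel_models=channel_models, condition=condition,
        time_point=time_point,
    )


def write_tracks(ts: TrackSet, path: str | Path | io.TextIOBase) -> None:
    """Write a TrackSet to CSV, re-readable by :func:`read_tracks`.

    Coordinates are written with 6 decimal places (sub-nm resolution in μm
    units), which makes the round trip lossless at the precision any tracker
    reports.
    """
    df = ts.to_frame()
    df.to_csv(path, index=False, float_format="%.6f")


def filter_min_length(ts: TrackSet, min_frames: int = 10) -> TrackSet:
    """Keep only trajectories with at least ``min_frames`` localizations.

    The quantitative analyses use trajectories of ≥ 10 frames; shorter
    tracks are dominated by molecules transiently colliding with the
    membrane and by localization noise.
    """
    if min_frames < 2:
        raise ValueError("min_frames must be >= 2")
    kept = [t for t in ts.trajectories if t.n_frames >= min_frames]
    removed = len(ts.trajectories) - len(kept)
    if removed:
        warnings.warn(
            f"filter_min_length: removed {removed} trajectories shorter than "
            f"{min_frames} frames",
            stacklevel=2,
        )
    return replace(ts, trajectories=kept)


def load_config(path: str | Path) -> dict:
    """Load a flat key-value (YAML) config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise TrackFormatError("config file must contain a key-value mapping")
    return cfg


def save_config(cfg: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=False)
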