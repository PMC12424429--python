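"""Transient-trapping detection and per-cell trapping statistics.

A transient trapping event is a stretch of ≥ ``min_event_frames`` consecutive
localizations confined within a circular zone of radius ``radius`` (default
50 nm, i.e. a 100-nm-diameter region) around the event centroid.  Detection
uses a greedy two-pass scan per trajectory:

* Pass 1 anchors a candidate window at a frame and grows it one frame at a
  time, recomputing the running centroid and requiring *every* member to lie
  within the radius of it; the first frame that breaks confinement stops
  growth.
* Pass 2 re-verifies all members against the final centroid, trimming
  trailing frames that violate the radius, and accepts the window if at
  least ``min_event_frames`` remain.  Scanning resumes at the frame after an
  accepted event, so events never overlap.

A single excursion frame terminates an event (no tolerance); the synthetic
generator can be used to quantify the fragmentation this causes.

The spatial spread of an event is the radial SD of its positions about the
centroid.  Localization noise inflates that spread; with isotropic per-axis
precision σ the expected inflation is 2σ² in variance, so the
precision-corrected zone size is sqrt(max(raw_sd² − 2σ², 0)) and the zone
area is reported as corrected_sd² (in multiples of π nm²).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .trajio import NM_PER_UM, TrackSet, Trajectory


@dataclass(frozen=True)
class DetectorParams:
    """Trapping-detector criteria.

    radius : confinement radius in nm (100-nm-diameter zone by default)
    min_event_frames : threshold residency, frames (5 frames = 166.7 ms)
    min_traj_frames : minimum trajectory length entering the analysis
    """

    radius: float = 50.0
    min_event_frames: int = 5
    min_traj_frames: int = 10

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("radius must be > 0")
        if self.min_event_frames < 2:
            raise ValueError("min_event_frames must be >= 2")


@dataclass
class TrappingEvent:
    """One detected confinement episode (frames inclusive)."""

    cell_id: str
    channel: str
    trajectory_id: str
    start_frame: int
    end_frame: int
    duration: float
    centroid: tuple[float, float]
    raw_sd: float
    corrected_sd: float
    zone_area_pi: float

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


def zone_size(
    positions_um: np.ndarray, sigma_axis: float
) -> tuple[float, float, float]:
    """Raw and precision-corrected zone size (nm) of a set of positions.

    raw_sd is the RMS distance of the positions from their centroid, i.e.
    the SD of the distances between the mean position during the trapping
    period and the individual positions.  The correction subtracts the
    localization variance in quadrature (2σ² for isotropic per-axis noise
    σ), clipping at zero; zone_area_pi = corrected_sd², so an event of
    corrected SD 25.24 nm is reported as a 637.1π nm² zone.
    """
    xy = np.asarray(positions_um, dtype=float) * NM_PER_UM
    c = xy.mean(axis=0)
    raw_var = float(np.mean(np.sum((xy - c) ** 2, axis=1)))
    raw_sd = np.sqrt(raw_var)
    corr_var = max(raw_var - 2.0 * sigma_axis**2, 0.0)
    corrected_sd = np.sqrt(corr_var)
    return raw_sd, corrected_sd, corrected_sd**2


def detect_events(
    traj: Trajectory,
    params: DetectorParams = DetectorParams(),
    sigma_axis: float = 0.0,
) -> list[TrappingEvent]:
    """Greedy scan for maximal non-overlapping trapping events.

    ``sigma_axis`` (nm) is the per-axis localization precision used for the
    zone-size correction only; detection itself uses the raw coordinates.
    """
    if traj.n_frames < params.min_traj_frames:
        return []
    xy = traj.xy * NM_PER_UM  # work in nm
    n = len(xy)
    r = params.radius
    m = params.min_event_frames
    events: list[TrappingEvent] = []
    i = 0
    while i <= n - m:
        # pass 1: grow while every member stays within r of the running centroid
        end = i  # inclusive; start from the singleton window
        csum = xy[i].copy()
        while end + 1 < n:
            cand = end + 1
            csum_new = csum + xy[cand]
            centroid = csum_new / (cand - i + 1)
            win = xy[i : cand + 1]
            if np.max(np.sum((win - centroid) ** 2, axis=1)) <= r * r:
                end = cand
                csum = csum_new
            else:
                break
        # pass 2: verify against the final centroid, trimming trailing frames
        while end - i + 1 >= m:
            win = xy[i : end + 1]
            centroid = win.mean(axis=0)
            if np.max(np.sum((win - centroid) ** 2, axis=1)) <= r * r:
                break
            end -= 1
        length = end - i + 1
        if length >= m:
            win_um = traj.xy[i : end + 1]
            raw_sd, corrected_sd, area_pi = zone_size(win_um, sigma_axis)
            centroid_um = win_um.mean(axis=0)
            events.append(
                TrappingEvent(
                    cell_id=traj.cell_id,
                    channel=traj.channel,
                    trajectory_id=traj.trajectory_id,
                    start_frame=int(traj.frames[i]),
                    end_frame=int(traj.frames[end]),
                    duration=length * traj.dt,
                    centroid=(float(centroid_um[0]), float(centroid_um[1])),
                    raw_sd=raw_sd,
                    corrected_sd=corrected_sd,
                    zone_area_pi=area_pi,
                )
            )
            i = end + 1
        else:
            i += 1
    return events


def detect_all(
    ts: TrackSet,
    params: DetectorParams = DetectorParams(),
    sigma_axis: float | None = None,
) -> list[TrappingEvent]:
    """Run the detector over a TrackSet.

    When ``sigma_axis`` is None, each trajectory uses its channel's
    precision from the TrackSet's channel models (0 if unknown, i.e. no
    zone-size correction).
    """
    events: list[TrappingEvent] = []
    for t in ts:
        if sigma_axis is None:
            sig = ts.sigma_axis(t.channel, default=0.0)
        else:
            sig = sigma_axis
        events.extend(detect_events(t, params, sig))
    return events


def events_table(events: list[TrappingEvent]) -> pd.DataFrame:
    cols = [
        "cell_id", "channel", "trajectory_id", "start_frame", "end_frame",
        "n_frames", "duration", "raw_sd", "corrected_sd", "zone_area_pi",
    ]
    rows = [
        {
            "cell_id": e.cell_id,
            "channel": e.channel,
            "trajectory_id": e.trajectory_id,
            "start_frame": e.start_frame,
            "end_frame": e.end_frame,
            "n_frames": e.n_frames,
            "duration": e.duration,
            "raw_sd": e.raw_sd,
            "corrected_sd": e.corrected_sd,
            "zone_area_pi": e.zone_area_pi,
        }
        for e in events
    ]
    return pd.DataFrame(rows, columns=cols)


def summarize_cell(
    ts: TrackSet, events: list[TrappingEvent]
) -> pd.DataFrame:
    """Per-cell temporal fraction (%), frequency (events/s) and counts.

    temporal_fraction = 100 × (total event time) / (total tracked time);
    frequency = (event count) / (total tracked time).  The tracked time of a
    cell sums the durations of its (already length-filtered) trajectories.
    """
    track_time: dict[str, float] = {}
    for t in ts:
        track_time[t.cell_id] = track_time.get(t.cell_id, 0.0) + t.duration
    if not track_time or all(v <= 0 for v in track_time.values()):
        raise ValueError("zero total tracked time")
    trapped: dict[str, float] = {c: 0.0 for c in track_time}
    counts: dict[str, int] = {c: 0 for c in track_time}
    for e in events:
        if e.cell_id not in track_time:
            raise ValueError(
                f"event cell {e.cell_id!r} not present in the TrackSet"
            )
        trapped[e.cell_id] += e.duration
        counts[e.cell_id] += 1
    rows = [
        {
            "cell_id": c,
            "temporal_fraction": 100.0 * trapped[c] / track_time[c],
            "frequency": counts[c] / track_time[c],
            "event_count": counts[c],
            "total_track_time": track_time[c],
        }
        for c in track_time
    ]
    return pd.DataFrame(rows)


def duration_and_size_tables(events: list[TrappingEvent]) -> pd.DataFrame:
    """Paired (duration s, zone_area_pi nm²) table for scatter/correlation."""
    return pd.DataFrame(
        {
            "duration": [e.duration for e in events],
            "zone_area_pi": [e.zone_area_pi for e in events],
        }
    )


class TrappingModel:
    """Transient-trapping analysis of a TrackSet.

    ``fit()`` runs the confinement detector over every trajectory that
    passes the length filter and returns :class:`TrappingResults` with the
    event table, per-cell summaries, and the duration/zone-size statistics.
    """

    def __init__(
        self,
        tracks: TrackSet,
        params: DetectorParams = DetectorParams(),
        sigma_axis: float | None = None,
    ):
        self.tracks = tracks
        self.params = params
        self.sigma_axis = sigma_axis

    def fit(self) -> "TrappingResults":
        from .trajio import filter_min_length
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            ts = filter_min_length(self.tracks, self.params.min_traj_frames)
        events = detect_all(ts, self.params, self.sigma_axis)
        cells = summarize_cell(ts, events)
        return TrappingResults(self, ts, events, cells)


class TrappingResults:
    def __init__(
        self,
        model: TrappingModel,
        filtered: TrackSet,
        events: list[TrappingEvent],
        cell_summary: pd.DataFrame,
    ):
        self.model = model
        self.filtered = filtered
        self.events = events
        self.cell_summary = cell_summary

    @property
    def events_table(self) -> pd.DataFrame:
        return events_table(self.events)

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def mean_temporal_fraction(self) -> float:
        """Mean over cells of the per-cell temporal fraction (%)."""
        return float(self.cell_summary["temporal_fraction"].mean())

    @property
    def mean_frequency(self) -> float:
        return float(self.cell_summary["frequency"].mean())

    @property
    def mean_duration(self) -> float:
        """Mean detected event duration in seconds (nan if no events)."""
        if not self.events:
            return float("nan")
        return float(np.mean([e.duration for e in self.events]))

    def duration_size_correlation(self) -> tuple[float, float]:
        """Spearman ρ (and p) between event duration and zone area."""
        tab = duration_and_size_tables(self.events)
        if len(tab) < 3:
            return float("nan"), float("nan")
        rho, p = sps.spearmanr(tab["duration"], tab["zone_area_pi"])
        return float(rho), float(p)

    def summary(self) -> str:
        p = self.model.params
        rho, _ = self.duration_size_correlation()
        lines = [
            "Transient-trapping analysis",
            "-" * 46,
            f"detector             {p.radius:.0f} nm radius, "
            f">= {p.min_event_frames} frames",
            f"trajectories         {len(self.filtered)} (>= {p.min_traj_frames} frames)",
            f"cells                {len(self.cell_summary)}",
            f"events               {self.n_events}",
            f"mean duration        {self.mean_duration * 1e3:.1f} ms",
            f"mean temporal frac.  {self.mean_temporal_fraction:.2f} %",
            f"mean frequency       {self.mean_frequency:.3f} events/s",
            f"duration-size rho    {rho:.3f}",
        ]
        return "\n".join(lines)
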