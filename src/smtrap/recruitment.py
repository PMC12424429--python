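"""Membrane-recruitment quantification from spot intensities.

Cytoplasmic signaling proteins (e.g. the exchange factor SOS1 or the kinase
BRAF) are recruited to the plasma membrane on stimulation.  Recruitment is
quantified per cell as the sum of background-subtracted spot intensities
over molecules that persist on the membrane (trajectories of at least
``min_frames`` localizations; shorter tracks are transient cytoplasmic
collisions), expressed as a ratio to the value at a reference time point
(1 min after stimulation by convention), then averaged across cells.

The phosphatidylserine-probe assay is summarized by a normalized spot
density: spot count divided by both the whole-cell probe intensity (an
expression-level proxy) and the observation area.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajio import TrackSet


@dataclass
class SpotDensityRecord:
    """Spot count normalized to expression level and observation area."""

    count: int
    whole_cell_intensity: float
    area: float
    normalized_density: float


def normalized_spot_density(
    count: int, whole_cell_intensity: float, area: float
) -> SpotDensityRecord:
    """count / (whole-cell intensity × observation area)."""
    if count < 0:
        raise ValueError("count must be >= 0")
    if not whole_cell_intensity > 0 or not area > 0:
        raise ValueError("intensity and area must be > 0")
    return SpotDensityRecord(
        count=count,
        whole_cell_intensity=whole_cell_intensity,
        area=area,
        normalized_density=count / (whole_cell_intensity * area),
    )


def _cell_intensity_sums(
    ts: TrackSet,
    background: float,
    min_frames: int,
    cmp: str,
) -> dict[str, float]:
    op = {">=": operator.ge, ">": operator.gt}[cmp]
    sums: dict[str, float] = {}
    for t in ts:
        if not op(t.n_frames, min_frames):
            continue
        s = float(np.sum(t.intensity - background))
        sums[t.cell_id] = sums.get(t.cell_id, 0.0) + s
    return sums


def recruitment_timecourse(
    tracksets: dict[str, TrackSet],
    background: float = 0.0,
    reference: str = "1min",
    min_frames: int = 10,
    length_cmp: str = ">=",
) -> pd.DataFrame:
    """Per-time-point mean ± SEM recruitment ratio across cells.

    ``tracksets`` maps time-point labels to TrackSets; ``reference`` names
    the time point whose per-cell intensity normalizes the others (its mean
    ratio is 1 by construction).  Only trajectories persisting ``min_frames``
    frames count as recruited; the comparison operator is configurable
    (``">="`` by default, ``">"`` for the strictly-longer-than reading).
    Cells are matched across time points by cell_id, and a cell enters a
    time point's ratio only if it has a positive reference intensity.
    """
    if reference not in tracksets:
        raise ValueError(f"reference time point {reference!r} missing")
    if length_cmp not in (">=", ">"):
        raise ValueError("length_cmp must be '>=' or '>'")
    ref_sums = _cell_intensity_sums(
        tracksets[reference], background, min_frames, length_cmp
    )
    rows = []
    for label, ts in tracksets.items():
        sums = _cell_intensity_sums(ts, background, min_frames, length_cmp)
        ratios = [
            sums[c] / ref_sums[c]
            for c in sums
            if c in ref_sums and ref_sums[c] > 0
        ]
        n = len(ratios)
        if n == 0:
            raise ValueError(
                f"time point {label!r} shares no usable cells with the "
                "reference"
            )
        mean = float(np.mean(ratios))
        sem = float(np.std(ratios, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append(
            {"time": label, "mean_ratio": mean, "sem": sem, "n_cells": n}
        )
    return pd.DataFrame(rows)


class RecruitmentModel:
    """Recruitment time-course analysis over per-time-point TrackSets."""

    def __init__(
        self,
        tracksets: dict[str, TrackSet],
        background: float = 0.0,
        reference: str = "1min",
        min_frames: int = 10,
        length_cmp: str = ">=",
    ):
        self.tracksets = tracksets
        self.background = background
        self.reference = reference
        self.min_frames = min_frames
        self.length_cmp = length_cmp

    def fit(self) -> "RecruitmentResults":
        table = recruitment_timecourse(
            self.tracksets,
            self.background,
            self.reference,
            self.min_frames,
            self.length_cmp,
        )
        return RecruitmentResults(self, table)


class RecruitmentResults:
    def __init__(self, model: RecruitmentModel, table: pd.DataFrame):
        self.model = model
        self.table = table

    def summary(self) -> str:
        lines = [
            "Recruitment time course (intensity-sum ratio)",
            "-" * 46,
            f"reference            {self.model.reference}",
            f"{'time':<10}{'ratio':>8}{'sem':>8}{'cells':>7}",
        ]
        for _, r in self.table.iterrows():
            lines.append(
                f"{r['time']:<10}{r['mean_ratio']:>8.3f}{r['sem']:>8.3f}"
                f"{int(r['n_cells']):>7}"
            )
        return "\n".join(lines)
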