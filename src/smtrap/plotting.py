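"""Figure helpers mirroring the field's reporting conventions."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers may switch backends first
import matplotlib.pyplot as plt
import numpy as np

from .msd import MSDProfile
from .stats import box_summary


def plot_msd(profile: MSDProfile, ax=None):
    """MSD versus lag time, with the fitted-lag region visible."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(profile.delta_t * 1e3, profile.msd, "o-", ms=4)
    ax.set_xlabel("lag time (ms)")
    ax.set_ylabel(r"MSD ($\mu m^2$)")
    return ax


def plot_box(groups: dict[str, np.ndarray], ylabel: str = "", ax=None):
    """Box-and-whisker plot (1.5×IQR whiskers, mean marked with a circle)."""
    if ax is None:
        _, ax = plt.subplots()
    labels = list(groups)
    data = [np.asarray(groups[k], float) for k in labels]
    ax.boxplot(data, tick_labels=labels, whis=1.5, showmeans=True,
               meanprops={"marker": "o"})
    ax.set_ylabel(ylabel)
    return ax


def plot_duration_histogram(durations_s, ax=None, bin_ms: float = 33.3):
    """Histogram of trapping-event durations in ms."""
    if ax is None:
        _, ax = plt.subplots()
    d = np.asarray(durations_s, float) * 1e3
    edges = np.arange(0.0, d.max() + 2 * bin_ms, bin_ms)
    ax.hist(d, bins=edges)
    ax.set_xlabel("trapping duration (ms)")
    ax.set_ylabel("events")
    return ax


def plot_duration_vs_zone(table, rho: float | None = None, ax=None):
    """Scatter of zone area (π·nm² multiples) against event duration."""
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(table["duration"] * 1e3, table["zone_area_pi"], s=6, alpha=0.4)
    ax.set_xlabel("trapping duration (ms)")
    ax.set_ylabel(r"zone area ($\pi\,nm^2$)")
    if rho is not None:
        ax.set_title(rf"$\rho$ = {rho:.3f}")
    return ax
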