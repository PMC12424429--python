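"""Synthetic single-molecule trajectories with known ground truth.

The generator emulates video-rate (33-ms frame) 2-D TIRF tracking of
membrane molecules that alternate between free Brownian diffusion and
transient trapping:

* a continuous-time two-state Markov chain with exponential dwell times
  (rounded to whole frames; switching happens at frame boundaries) sets the
  hidden free/trapped state sequence;
* in the free state the molecule takes Gaussian steps with per-axis variance
  2·D·dt (so MSD = 4·D·Δt); in the trapped state positions are i.i.d.
  Gaussian scatter (per-axis SD ``trap_conf_sd``) about a trap center fixed
  at the entry position of the event;
* every position receives i.i.d. per-axis localization noise ``sigma_axis``;
* photobleaching truncates the track geometrically with mean
  ``bleach_lifetime``/dt frames, capped at the movie length (300 frames of a
  10-s video-rate movie).

Ground-truth state labels are returned so detector recall/precision and
occupancy recovery can be measured exactly.  Two closed-form "truncation
oracles" predict what the 5-frame detector can see of exponential dwells:
because the exponential is memoryless, dwells longer than the threshold time
T have mean T + τ, and the fraction of trapped *time* lying in dwells ≥ T is
e^(−T/τ)(1 + T/τ) (length-biased sampling).  These let a preset's occupancy
be calibrated so the *detected* temporal fraction matches a target value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .trajio import DEFAULT_DT, NM_PER_UM, ChannelModel, TrackSet, Trajectory
from .trapping import DetectorParams

MOVIE_FRAMES = 300


@dataclass
class SimulationPreset:
    """Generative parameters for one experimental condition.

    Exactly one of ``occupancy`` (stationary fraction of time trapped) and
    ``free_dwell_mean`` may be given; the other is derived from
    occupancy = trap_dwell_mean / (trap_dwell_mean + free_dwell_mean).
    """

    d_free: float = 0.53  # um^2/s
    trap_conf_sd: float = 10.0  # nm, per-axis true scatter in a trap
    trap_dwell_mean: float = 0.17  # s, exponential
    occupancy: float | None = None  # fraction of time trapped
    free_dwell_mean: float | None = None  # s, exponential
    sigma_axis: float = 14.0  # nm, per-axis localization noise
    dt: float = DEFAULT_DT  # s
    bleach_lifetime: float = 10.4  # s
    movie_frames: int = MOVIE_FRAMES
    n_cells: int = 20
    trajectories_per_cell: int = 200
    channel: str = "green"
    seed: int | None = None
    comment: str = ""

    def __post_init__(self) -> None:
        if self.d_free < 0 or self.trap_conf_sd < 0 or self.sigma_axis < 0:
            raise ValueError("scales must be >= 0")
        if not (self.trap_dwell_mean > 0 and self.dt > 0
                and self.bleach_lifetime > 0):
            raise ValueError("dwell mean, dt and bleach lifetime must be > 0")
        if self.occupancy is None and self.free_dwell_mean is None:
            self.occupancy = 0.0
        if self.occupancy is not None and self.free_dwell_mean is not None:
            implied = self.trap_dwell_mean / (
                self.trap_dwell_mean + self.free_dwell_mean
            )
            if not math.isclose(implied, self.occupancy, rel_tol=1e-6):
                raise ValueError(
                    "occupancy and free_dwell_mean are inconsistent; give one"
                )
        if self.occupancy is None:
            self.occupancy = self.trap_dwell_mean / (
                self.trap_dwell_mean + self.free_dwell_mean
            )
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")
        if self.free_dwell_mean is None and 0.0 < self.occupancy < 1.0:
            self.free_dwell_mean = (
                self.trap_dwell_mean * (1.0 - self.occupancy) / self.occupancy
            )

    @property
    def channel_model(self) -> ChannelModel:
        return ChannelModel(
            sigma_axis=max(self.sigma_axis, 1e-9),
            bleach_lifetime=self.bleach_lifetime,
        )


@dataclass
class PairPreset:
    """Dual-color pairing parameters for colocalization simulations."""

    bound_fraction: float = 0.0
    registration_offset: float = 0.0  # nm, systematic inter-channel shift
    sigma_ch1: float = 14.0  # nm
    sigma_ch2: float = 18.7  # nm
    roi_side: float = 10.0  # um, molecules start uniformly in this square

    def __post_init__(self) -> None:
        if not 0.0 <= self.bound_fraction <= 1.0:
            raise ValueError("bound_fraction must lie in [0, 1]")
        if self.sigma_ch1 < 0 or self.sigma_ch2 < 0 or self.roi_side <= 0:
            raise ValueError("invalid pair preset scales")


def _bleach_length(p: SimulationPreset, rng: np.random.Generator) -> int:
    prob = min(max(p.dt / p.bleach_lifetime, 1e-12), 1.0)
    length = int(rng.geometric(prob))
    return max(2, min(length, p.movie_frames))


def _state_sequence(
    p: SimulationPreset, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Frame-wise hidden states (True = trapped), dwells in whole frames."""
    if p.occupancy <= 0.0:
        return np.zeros(n, dtype=bool)
    if p.occupancy >= 1.0:
        return np.ones(n, dtype=bool)
    states = np.empty(n, dtype=bool)
    trapped = bool(rng.random() < p.occupancy)
    i = 0
    while i < n:
        mean = p.trap_dwell_mean if trapped else p.free_dwell_mean
        frames = max(1, int(round(rng.exponential(mean) / p.dt)))
        j = min(n, i + frames)
        states[i:j] = trapped
        trapped = not trapped
        i = j
    return states


def _true_positions(
    p: SimulationPreset, states: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    n = len(states)
    xy = np.empty((n, 2))
    step_sd = math.sqrt(2.0 * p.d_free * p.dt)  # um, per axis
    conf_sd = p.trap_conf_sd / NM_PER_UM
    cur = np.zeros(2)
    i = 0
    while i < n:
        j = i
        while j < n and states[j] == states[i]:
            j += 1
        m = j - i
        if states[i]:
            # the molecule diffuses into the trap during the switching frame
            # interval, so the center sits one free step beyond the last
            # free-state localization; positions then scatter about it
            if i > 0:
                cur = cur + rng.normal(0.0, step_sd, size=2)
            xy[i:j] = cur + rng.normal(0.0, conf_sd, size=(m, 2))
            # free diffusion resumes from the trap center
        else:
            steps = rng.normal(0.0, step_sd, size=(m, 2))
            xy[i:j] = cur + np.cumsum(steps, axis=0)
            cur = xy[j - 1]
        i = j
    return xy


def simulate_trajectory(
    p: SimulationPreset,
    rng: np.random.Generator,
    cell_id: str = "cell000",
    trajectory_id: str = "t0000",
) -> tuple[Trajectory, np.ndarray]:
    """One trajectory plus its ground-truth state labels (True = trapped)."""
    n = _bleach_length(p, rng)
    states = _state_sequence(p, n, rng)
    true_xy = _true_positions(p, states, rng)
    noise = rng.normal(0.0, p.sigma_axis / NM_PER_UM, size=true_xy.shape)
    traj = Trajectory(
        cell_id=cell_id,
        channel=p.channel,
        trajectory_id=trajectory_id,
        frames=np.arange(n),
        xy=true_xy + noise,
        dt=p.dt,
        intensity=np.ones(n),
    )
    return traj, states


def simulate_experiment(
    p: SimulationPreset, seed: int | None = None
) -> TrackSet:
    """n_cells × trajectories_per_cell trajectories with per-cell substreams.

    Cells draw from independent child streams of one seed sequence, so the
    whole experiment is reproducible bit-exactly from (preset, seed) and the
    cells are statistically independent.
    """
    if seed is None:
        seed = p.seed
    ss = np.random.SeedSequence(seed)
    trajectories = []
    for ci, child in enumerate(ss.spawn(p.n_cells)):
        rng = np.random.default_rng(child)
        for ti in range(p.trajectories_per_cell):
            traj, _ = simulate_trajectory(
                p, rng, cell_id=f"cell{ci:03d}", trajectory_id=f"t{ti:04d}"
            )
            trajectories.append(traj)
    return TrackSet(
        trajectories=trajectories,
        dt=p.dt,
        channel_models={p.channel: p.channel_model},
        condition=p.comment or "simulated",
    )


def simulate_experiment_with_states(
    p: SimulationPreset, seed: int | None = None
) -> tuple[TrackSet, dict[tuple[str, str], np.ndarray]]:
    """Like :func:`simulate_experiment` but also returns the hidden states."""
    if seed is None:
        seed = p.seed
    ss = np.random.SeedSequence(seed)
    trajectories = []
    states: dict[tuple[str, str], np.ndarray] = {}
    for ci, child in enumerate(ss.spawn(p.n_cells)):
        rng = np.random.default_rng(child)
        for ti in range(p.trajectories_per_cell):
            cid, tid = f"cell{ci:03d}", f"t{ti:04d}"
            traj, st = simulate_trajectory(p, rng, cell_id=cid,
                                           trajectory_id=tid)
            trajectories.append(traj)
            states[(cid, tid)] = st
    ts = TrackSet(
        trajectories=trajectories,
        dt=p.dt,
        channel_models={p.channel: p.channel_model},
        condition=p.comment or "simulated",
    )
    return ts, states


def simulate_pair(
    pp: PairPreset, base: SimulationPreset, seed: int | None = None
) -> TrackSet:
    """Two-channel TrackSet for colocalization nulls and positives.

    A fraction ``bound_fraction`` of channel-2 molecules rides the *true*
    position sequence of a channel-1 molecule (shifted by the registration
    offset); the remainder are independent molecules.  The two channels
    receive independent localization noise with their own precisions.
    Molecules start uniformly in a ``roi_side`` × ``roi_side`` μm region.
    """
    if seed is None:
        seed = base.seed
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    trajectories = []
    n_mol = base.n_cells * base.trajectories_per_cell
    n_bound = int(round(pp.bound_fraction * n_mol))
    off = np.array([pp.registration_offset, 0.0]) / NM_PER_UM
    for k in range(n_mol):
        start = rng.uniform(0.0, pp.roi_side, size=2)
        n = _bleach_length(base, rng)
        st = _state_sequence(base, n, rng)
        true1 = _true_positions(base, st, rng) + start
        noise1 = rng.normal(0.0, pp.sigma_ch1 / NM_PER_UM, size=true1.shape)
        trajectories.append(
            Trajectory(
                cell_id="cell000", channel="ch1", trajectory_id=f"a{k:04d}",
                frames=np.arange(n), xy=true1 + noise1, dt=base.dt,
            )
        )
        if k < n_bound:
            true2 = true1 + off
        else:
            start2 = rng.uniform(0.0, pp.roi_side, size=2)
            st2 = _state_sequence(base, n, rng)
            true2 = _true_positions(base, st2, rng) + start2
        noise2 = rng.normal(0.0, pp.sigma_ch2 / NM_PER_UM, size=true2.shape)
        trajectories.append(
            Trajectory(
                cell_id="cell000", channel="ch2", trajectory_id=f"b{k:04d}",
                frames=np.arange(n), xy=true2 + noise2, dt=base.dt,
            )
        )
    return TrackSet(
        trajectories=trajectories,
        dt=base.dt,
        channel_models={
            "ch1": ChannelModel(max(pp.sigma_ch1, 1e-9), base.bleach_lifetime),
            "ch2": ChannelModel(max(pp.sigma_ch2, 1e-9), base.bleach_lifetime),
        },
        condition="simulated-pair",
    )


def _length_bias_factor(T: float, tau: float) -> float:
    return math.exp(-T / tau) * (1.0 + T / tau)


def expected_detected_fraction(
    p: SimulationPreset, dp: DetectorParams
) -> float:
    """Fraction of *time* the detector can attribute to trapping.

    For exponential dwells with mean τ, the share of trapped time lying in
    dwells of at least the threshold time T = min_event_frames·dt is
    e^(−T/τ)(1 + T/τ) (length-biased truncation), so the detectable temporal
    fraction is occupancy × that factor.  Excursion-induced fragmentation is
    ignored, making this an upper bound; it is tight when trap_conf_sd is
    ≤ ~10 nm so that excursions beyond the detection radius are rare.
    """
    T = dp.min_event_frames * p.dt
    return p.occupancy * _length_bias_factor(T, p.trap_dwell_mean)


def expected_detected_mean_duration(
    dp: DetectorParams, tau: float, dt: float = DEFAULT_DT
) -> float:
    """Mean of an exponential(τ) dwell conditioned on exceeding T: T + τ."""
    return dp.min_event_frames * dt + tau


def calibrate_occupancy(
    target_detected_fraction: float,
    p: SimulationPreset,
    dp: DetectorParams,
) -> float:
    """Occupancy whose expected detected temporal fraction hits the target.

    Inverts :func:`expected_detected_fraction`; raises when the target is
    infeasible (would require occupancy > 1).
    """
    if target_detected_fraction < 0:
        raise ValueError("target fraction must be >= 0")
    if target_detected_fraction == 0:
        return 0.0
    T = dp.min_event_frames * p.dt
    occ = target_detected_fraction / _length_bias_factor(T, p.trap_dwell_mean)
    if occ > 1.0:
        raise ValueError(
            f"target {target_detected_fraction} infeasible for "
            f"tau = {p.trap_dwell_mean}: implied occupancy {occ:.3f} > 1"
        )
    return occ


def load_presets() -> dict[str, SimulationPreset]:
    """Built-in presets emulating the studied experimental conditions."""
    text = resources.files("smtrap").joinpath("presets.yaml").read_text()
    raw = yaml.safe_load(text)
    return {name: SimulationPreset(**kw) for name, kw in raw.items()}


def get_preset(name: str) -> SimulationPreset:
    presets = load_presets()
    try:
        return presets[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(presets))}"
        ) from None
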