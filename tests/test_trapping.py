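import itertools
import math

import numpy as np
import pytest

from smtrap.simulate import SimulationPreset, simulate_experiment
from smtrap.trajio import DEFAULT_DT, NM_PER_UM, TrackSet, Trajectory
from smtrap.trapping import (
    DetectorParams,
    TrappingModel,
    detect_all,
    detect_events,
    duration_and_size_tables,
    summarize_cell,
    zone_size,
)

from conftest import brownian_track


def _traj(xy, dt=DEFAULT_DT, tid="t0", cell="c0"):
    return Trajectory(cell, "g", tid, np.arange(len(xy)),
                      np.asarray(xy, float), dt)


def qualifying_windows_bruteforce(xy_um, radius_nm, min_frames):
    """All (start, end) windows whose members lie within radius of the
    window centroid — the exhaustive oracle for event membership."""
    xy = np.asarray(xy_um) * NM_PER_UM
    out = []
    n = len(xy)
    for s, e in itertools.combinations(range(n + 1), 2):
        e -= 1
        if e - s + 1 < min_frames:
            continue
        win = xy[s:e + 1]
        c = win.mean(axis=0)
        if np.max(np.sum((win - c) ** 2, axis=1)) <= radius_nm**2:
            out.append((s, e))
    return out


class TestDetectEvents:
    def test_identical_points_single_event(self):
        xy = np.tile([1.0, 2.0], (10, 1))
        events = detect_events(_traj(xy))
        assert len(events) == 1
        e = events[0]
        assert (e.start_frame, e.end_frame) == (0, 9)
        assert e.duration == pytest.approx(10 * DEFAULT_DT)
        assert e.raw_sd == 0.0

    def test_two_separated_confinements_match_bruteforce(self, rng):
        # frames 0-5 near origin, frame 6 far away, frames 7-12 near (1,0),
        # frames 13-14 far: two 6-frame events
        near0 = rng.uniform(-0.02, 0.02, size=(6, 2))
        near1 = np.array([1.0, 0.0]) + rng.uniform(-0.02, 0.02, size=(6, 2))
        xy = np.vstack([near0, [[1.0, 1.0]], near1, [[3.0, 3.0]], [[5.0, 5.0]]])
        events = detect_events(_traj(xy), DetectorParams(min_traj_frames=10))
        spans = [(e.start_frame, e.end_frame) for e in events]
        assert spans == [(0, 5), (7, 12)]
        # the detected spans are exactly the maximal qualifying windows
        wins = qualifying_windows_bruteforce(xy, 50.0, 5)
        maximal = [w for w in wins
                   if not any(o != w and o[0] <= w[0] and w[1] <= o[1]
                              for o in wins)]
        assert spans == maximal

    def test_short_trajectories_are_skipped(self):
        xy = np.zeros((8, 2))
        assert detect_events(_traj(xy), DetectorParams(min_traj_frames=10)) == []

    def test_no_event_on_fast_brownian_track(self, rng):
        t = brownian_track(100, 0.5, rng, sigma_nm=14.0)
        assert detect_events(t) == []

    def test_events_never_overlap_and_rerun_spans_event(self, rng):
        p = SimulationPreset(d_free=0.45, trap_conf_sd=8.0,
                             trap_dwell_mean=0.4, occupancy=0.3,
                             sigma_axis=10.0, n_cells=1,
                             trajectories_per_cell=30)
        ts = simulate_experiment(p, seed=7)
        for t in ts:
            events = detect_events(t, sigma_axis=10.0)
            for a, b in zip(events, events[1:]):
                assert a.end_frame < b.start_frame
            for e in events:
                i0 = e.start_frame - t.frames[0]
                sub = _traj(t.xy[i0:i0 + e.n_frames])
                if sub.n_frames >= 10:
                    re_ev = detect_events(sub)
                    assert len(re_ev) == 1
                    assert re_ev[0].n_frames == e.n_frames

    def test_translation_rotation_invariance(self, rng):
        p = SimulationPreset(d_free=0.3, trap_conf_sd=8.0,
                             trap_dwell_mean=0.3, occupancy=0.4,
                             n_cells=1, trajectories_per_cell=10)
        ts = simulate_experiment(p, seed=3)
        th = 1.1
        rot = np.array([[math.cos(th), -math.sin(th)],
                        [math.sin(th), math.cos(th)]])
        for t in ts:
            base = [(e.start_frame, e.end_frame) for e in detect_events(t)]
            moved = _traj(t.xy @ rot.T + np.array([7.0, -2.0]))
            assert [(e.start_frame, e.end_frame)
                    for e in detect_events(moved)] == base

    def test_monotonicity_in_radius_and_min_frames(self, rng):
        p = SimulationPreset(d_free=0.3, trap_conf_sd=12.0,
                             trap_dwell_mean=0.25, occupancy=0.35,
                             n_cells=1, trajectories_per_cell=40)
        ts = simulate_experiment(p, seed=11)

        def total_time(params):
            return sum(e.duration for e in detect_all(ts, params))

        t50 = total_time(DetectorParams(radius=50))
        assert total_time(DetectorParams(radius=80)) >= t50
        assert total_time(DetectorParams(min_event_frames=4)) >= t50


class TestZoneSize:
    def test_pure_noise_event_corrects_to_zero(self, rng):
        sigma = 14.0
        raws, cors = [], []
        for _ in range(400):
            pos = rng.normal(0, sigma / 1000, size=(8, 2))
            raw, cor, _ = zone_size(pos, sigma)
            raws.append(raw)
            cors.append(cor)
        # E[raw^2] = 2 sigma^2 (minus small centroid shrinkage)
        assert np.mean(np.square(raws)) == pytest.approx(2 * sigma**2,
                                                         rel=0.15)
        assert np.mean(np.square(cors)) < 0.25 * 2 * sigma**2

    @pytest.mark.parametrize("s_nm", [10.0, 20.0, 30.0])
    def test_quadrature_recovery_of_confinement_scatter(self, rng, s_nm):
        sigma = 14.0
        cors = []
        for _ in range(600):
            pos = (rng.normal(0, s_nm / 1000, size=(12, 2))
                   + rng.normal(0, sigma / 1000, size=(12, 2)))
            _, cor, _ = zone_size(pos, sigma)
            cors.append(cor**2)
        # radial SD of the true scatter is sqrt(2)*s
        assert np.sqrt(np.mean(cors)) == pytest.approx(
            math.sqrt(2) * s_nm, rel=0.15)

    def test_zone_area_reporting_convention(self):
        # a corrected radial SD of 25.24 nm is reported as a 637.1 pi nm^2 zone
        pos = np.array([[0.0, 0.0], [0.0252398, 0.0], [-0.0252398, 0.0],
                        [0.0, 0.0252398], [0.0, -0.0252398]])
        raw, cor, area_pi = zone_size(pos, sigma_axis=0.0)
        assert cor == pytest.approx(raw)
        assert area_pi == pytest.approx(cor**2)
        _, cor2, area2 = zone_size(pos * (25.24 / cor), sigma_axis=0.0)
        assert area2 == pytest.approx(637.1, abs=0.2)

    def test_corrected_never_exceeds_raw(self, rng):
        pos = rng.normal(0, 0.02, size=(10, 2))
        raw, cor, _ = zone_size(pos, sigma_axis=14.0)
        assert cor <= raw


class TestCellSummaries:
    def test_temporal_fraction_arithmetic(self, rng):
        xy = np.vstack([np.zeros((5, 2)),
                        np.cumsum(rng.normal(0, 0.3, size=(15, 2)), axis=0)
                        + 1.0])
        t = _traj(xy)
        events = detect_events(t)
        assert len(events) == 1 and events[0].n_frames == 5
        ts = TrackSet([t])
        summ = summarize_cell(ts, events)
        row = summ.iloc[0]
        assert row["temporal_fraction"] == pytest.approx(25.0)
        assert row["frequency"] == pytest.approx(1.0 / (20 * DEFAULT_DT))

    def test_no_events_gives_zero(self, rng):
        ts = TrackSet([brownian_track(20, 0.5, rng)])
        summ = summarize_cell(ts, [])
        assert summ.iloc[0]["temporal_fraction"] == 0.0
        assert summ.iloc[0]["frequency"] == 0.0

    def test_empty_trackset_errors(self):
        with pytest.raises(ValueError):
            summarize_cell(TrackSet([]), [])


class TestDurationSizeTable:
    def test_independent_size_and_duration_uncorrelated(self, rng):
        p = SimulationPreset(d_free=0.45, trap_conf_sd=10.0,
                             trap_dwell_mean=0.3, occupancy=0.3,
                             n_cells=4, trajectories_per_cell=120)
        res = TrappingModel(simulate_experiment(p, seed=5),
                            sigma_axis=14.0).fit()
        rho, _ = res.duration_size_correlation()
        # the generator draws scatter independently of dwell length
        assert abs(rho) < 0.08
        tab = duration_and_size_tables(res.events)
        assert len(tab) == res.n_events

    def test_empty_event_set(self):
        tab = duration_and_size_tables([])
        assert len(tab) == 0


class TestRecoveryProperties:
    def test_mean_event_duration_matches_truncation_oracle(self, rng):
        tau = 0.165
        p = SimulationPreset(d_free=0.53, trap_conf_sd=8.0,
                             trap_dwell_mean=tau, occupancy=0.25,
                             sigma_axis=14.0, bleach_lifetime=1e9,
                             movie_frames=1500, n_cells=2,
                             trajectories_per_cell=40)
        res = TrappingModel(simulate_experiment(p, seed=2),
                            sigma_axis=14.0).fit()
        expected = 5 * DEFAULT_DT + tau
        assert res.n_events > 1500
        assert res.mean_duration == pytest.approx(expected, rel=0.10)

    def test_free_brownian_false_positive_control(self, rng):
        p = SimulationPreset(d_free=0.5, occupancy=0.0, sigma_axis=14.0,
                             n_cells=2, trajectories_per_cell=300)
        res = TrappingModel(simulate_experiment(p, seed=9),
                            sigma_axis=14.0).fit()
        assert res.mean_temporal_fraction < 1.0
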