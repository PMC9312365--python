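"""Speed-series, wall-distance, occupancy and burst/coast segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cavehydro import (
    SegmentationParams,
    Trajectory,
    compute_speed_series,
    occupancy_summary,
    segment_burst_coast,
    wall_distance_series,
)
from cavehydro.core import Morphometry, TankGeometry


def make_traj(x, y=None, z=None, dt=0.02):
    x = np.asarray(x, float)
    n = len(x)
    y = np.zeros(n) if y is None else np.asarray(y, float)
    z = np.zeros(n) if z is None else np.asarray(z, float)
    return Trajectory(times=dt * np.arange(n), x=x, y=y, z=z, dt=dt)


class TestSpeedSeries:
    def test_stationary_fish_has_zero_speed(self):
        traj = make_traj(np.full(10, 3.0), np.full(10, 2.0), np.full(10, 1.0))
        s = compute_speed_series(traj)
        assert np.all(s.u == 0)

    def test_uniform_motion_recovers_speed(self):
        traj = make_traj([0.0, 0.02, 0.04], dt=0.02)
        s = compute_speed_series(traj)
        assert s.u == pytest.approx([1.0])
        assert s.vx == pytest.approx([1.0])

    def test_matches_per_sample_hand_evaluation(self):
        """Centered two-displacement formula re-evaluated sample by sample."""
        rng = np.random.default_rng(42)
        pos = rng.uniform(0, 30, size=(100, 3))
        dt = 0.02
        traj = make_traj(pos[:, 0], pos[:, 1], pos[:, 2], dt=dt)
        s = compute_speed_series(traj)
        for n in range(1, 99):
            comps = []
            for c in range(3):
                fwd = abs(pos[n + 1, c] - pos[n, c])
                bwd = abs(pos[n, c] - pos[n - 1, c])
                comps.append((fwd + bwd) / (2 * dt))
            u_expected = np.sqrt(sum(v**2 for v in comps))
            assert s.u[n - 1] == pytest.approx(u_expected, rel=1e-12)

    def test_endpoints_dropped(self):
        traj = make_traj(np.arange(10.0))
        assert len(compute_speed_series(traj)) == 8

    def test_insufficient_trajectory_raises(self):
        with pytest.raises(ValueError, match="insufficient"):
            compute_speed_series(make_traj([0.0, 1.0]))

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError, match="invalid time axis"):
            Trajectory(
                times=np.array([0.0, 0.02, 0.01]),
                x=np.zeros(3),
                y=np.zeros(3),
                z=np.zeros(3),
                dt=0.02,
            )

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1), st.floats(-50, 50))
    def test_translation_invariance(self, seed, offset):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0, 10, size=(20, 3))
        a = compute_speed_series(make_traj(*pos.T))
        b = compute_speed_series(make_traj(*(pos + offset).T))
        np.testing.assert_allclose(a.u, b.u, rtol=0, atol=1e-9)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_time_reversal_reverses_speeds(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0, 10, size=(20, 3))
        a = compute_speed_series(make_traj(*pos.T))
        b = compute_speed_series(make_traj(*pos[::-1].T))
        np.testing.assert_allclose(a.u, b.u[::-1], rtol=1e-12)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_speed_composition_exact(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0, 10, size=(20, 3))
        s = compute_speed_series(make_traj(*pos.T))
        np.testing.assert_allclose(
            s.u**2, s.vx**2 + s.vy**2 + s.vz**2, rtol=1e-12, atol=0
        )
        assert np.all(s.u >= 0)


class TestWallDistance:
    def test_tank_center(self, tank):
        traj = make_traj([20.0] * 3, [12.5] * 3, [4.0] * 3)
        assert wall_distance_series(traj, tank) == pytest.approx([12.5] * 3)

    def test_near_one_wall(self, tank):
        traj = make_traj([1.0] * 3, [12.5] * 3, [4.0] * 3)
        assert wall_distance_series(traj, tank) == pytest.approx([1.0] * 3)

    def test_matches_brute_force_over_planes(self, tank):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, tank.lx, 200)
        y = rng.uniform(0, tank.ly, 200)
        z = rng.uniform(0, tank.lz, 200)
        d = wall_distance_series(make_traj(x, y, z), tank)
        expected = [min(xi, tank.lx - xi, yi, tank.ly - yi) for xi, yi in zip(x, y)]
        np.testing.assert_allclose(d, expected, rtol=1e-12)

    def test_matches_shapely_boundary_distance(self, tank):
        """Independent geometric oracle: distance to the box boundary."""
        shapely = pytest.importorskip("shapely.geometry")
        box = shapely.box(0, 0, tank.lx, tank.ly)
        rng = np.random.default_rng(8)
        x = rng.uniform(0, tank.lx, 50)
        y = rng.uniform(0, tank.ly, 50)
        d = wall_distance_series(make_traj(x, y, np.full(50, 4.0)), tank)
        expected = [box.boundary.distance(shapely.Point(xi, yi)) for xi, yi in zip(x, y)]
        np.testing.assert_allclose(d, expected, rtol=1e-9)

    def test_slightly_outside_clamped_with_warning(self, tank):
        traj = make_traj([-0.1, 1.0, 2.0], [5.0] * 3, [4.0] * 3)
        with pytest.warns(UserWarning, match="clamped"):
            d = wall_distance_series(traj, tank)
        assert d[0] == 0.0

    def test_far_outside_raises_with_index(self, tank):
        traj = make_traj([5.0, -3.0, 2.0], [5.0] * 3, [4.0] * 3)
        with pytest.raises(ValueError, match="index 1"):
            wall_distance_series(traj, tank)

    def test_six_plane_option_includes_floor(self, tank):
        traj = make_traj([20.0] * 3, [12.5] * 3, [1.0] * 3)
        d = wall_distance_series(traj, tank, include_floor_surface=True)
        assert d == pytest.approx([1.0] * 3)


class TestOccupancy:
    def _series(self, dists, morph, u=None):
        n = len(dists)
        dt = 0.02
        traj = make_traj(np.linspace(0, 1, n + 2))
        s = compute_speed_series(traj)
        return s, np.asarray(dists, float)

    def test_all_near_wall_gives_fraction_one(self, morph):
        n = 500
        traj = make_traj(np.cumsum(np.full(n, 0.02)))
        s = compute_speed_series(traj)
        dists = np.full(n - 2, 0.1 * morph.bl)
        summ = occupancy_summary(s, dists, morph, bin_minutes=30)
        assert summ.table.near_wall_fraction.iloc[0] == 1.0

    def test_all_far_gives_fraction_zero(self, morph):
        n = 500
        traj = make_traj(np.cumsum(np.full(n, 0.02)))
        s = compute_speed_series(traj)
        dists = np.full(n - 2, 10 * morph.bl)
        summ = occupancy_summary(s, dists, morph)
        assert summ.table.near_wall_fraction.iloc[0] == 0.0

    def test_histograms_sum_to_one(self, morph):
        rng = np.random.default_rng(3)
        n = 1000
        traj = make_traj(np.cumsum(rng.uniform(0, 0.1, n)))
        s = compute_speed_series(traj)
        dists = rng.uniform(0, 12, n - 2)
        summ = occupancy_summary(s, dists, morph)
        for h in summ.dist_hists:
            assert np.nansum(h) == pytest.approx(1.0)

    def test_rescaling_invariance_in_bl_units(self, morph):
        """Scaling space and BL together leaves the occupancy unchanged."""
        rng = np.random.default_rng(4)
        n = 400
        traj = make_traj(np.cumsum(rng.uniform(0, 0.1, n)))
        s = compute_speed_series(traj)
        dists = rng.uniform(0, 12, n - 2)
        f1 = occupancy_summary(s, dists, morph).table.near_wall_fraction
        scale = 3.7
        big = Morphometry(
            bl=morph.bl * scale,
            bh=morph.bh * scale,
            bw=morph.bw * scale,
            area=morph.area,
            volume=morph.volume,
            mass=morph.mass,
        )
        f2 = occupancy_summary(s, dists * scale, big).table.near_wall_fraction
        np.testing.assert_allclose(f1, f2)


def synthetic_cycle(dt=0.02, rest=1.0, burst=0.8, coast=2.2, u0=1.0, upk=8.0):
    """Rest, linear burst ramp, quadratic-drag coast: one constructed cycle."""
    t_rest = np.full(int(rest / dt), 0.05)
    nb = int(burst / dt)
    t_burst = u0 + (upk - u0) * np.arange(1, nb + 1) / nb
    nc = int(coast / dt)
    beta = 0.324
    tau = dt * np.arange(1, nc + 1)
    t_coast = upk / (1 + beta * upk * tau)
    u = np.concatenate([t_rest, t_burst, t_coast])
    x = np.concatenate([[0.0], np.cumsum(u) * dt])
    n = len(u)
    traj = Trajectory(
        times=dt * np.arange(n), x=x[:n], y=np.zeros(n), z=np.zeros(n), dt=dt
    )
    return traj, rest, burst, coast


class TestSegmentation:
    def test_single_constructed_cycle_recovered(self):
        dt = 0.02
        traj, rest, burst, coast = synthetic_cycle(dt=dt)
        s = compute_speed_series(traj)
        events = segment_burst_coast(s)
        assert len(events) == 1
        e = events[0]
        # boundaries within a smoothing window of the construction
        tol = 0.2 + 2 * dt
        assert e.burst_duration == pytest.approx(burst, abs=tol)
        assert e.coast_duration == pytest.approx(coast, abs=tol)

    def test_monotone_decay_yields_no_bursts(self):
        dt = 0.02
        n = 200
        u = 8.0 / (1 + 0.3 * 8.0 * dt * np.arange(n))
        x = np.concatenate([[0.0], np.cumsum(u) * dt])[:n]
        traj = make_traj(x, dt=dt)
        s = compute_speed_series(traj)
        assert segment_burst_coast(s) == []
        coasts = segment_burst_coast(s, SegmentationParams(coast_only=True))
        assert len(coasts) == 1
        assert coasts[0].burst_duration == 0.0

    def test_fifty_cycle_session_means_recovered(self):
        """Generator/analyzer closure: drawn burst/coast means recovered."""
        from cavehydro.synth import gen_burst_coast_session

        traj, cycles = gen_burst_coast_session(50, seed=11)
        s = compute_speed_series(traj)
        events = segment_burst_coast(s)
        assert len(events) == 50
        rec_coast = np.mean([e.coast_duration for e in events])
        rec_cycle = np.mean([e.cycle_duration for e in events])
        true_coast = np.mean([c["coast_s"] for c in cycles])
        true_cycle = np.mean([c["cycle_s"] for c in cycles])
        se_coast = np.std([c["coast_s"] for c in cycles], ddof=1) / np.sqrt(50)
        se_cycle = np.std([c["cycle_s"] for c in cycles], ddof=1) / np.sqrt(50)
        assert abs(rec_coast - true_coast) < 2 * se_coast
        assert abs(rec_cycle - true_cycle) < 2 * se_cycle
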