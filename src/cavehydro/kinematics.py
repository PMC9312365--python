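"""Trajectory kinematics: speed series, wall distance, occupancy, burst/coast.

The instantaneous speed at an interior sample n is built from the two
displacements adjacent to it, per component,

    v_n,x = (|x_{n+1} - x_n| + |x_n - x_{n-1}|) / (2 Δt)

(and likewise for y and z), and the speed is the Euclidean composition

    u_n = sqrt(v_n,x^2 + v_n,y^2 + v_n,z^2).

The first and last samples have no centered estimate and are dropped.

Wall distance is, by default, the minimum distance to the four *vertical*
side walls of the tank (the floor and the free surface are excluded: in an
8 cm deep tank they carry no information about wall-following).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Morphometry, TankGeometry

__all__ = [
    "Trajectory",
    "SpeedSeries",
    "OccupancySummary",
    "BurstCoastEvent",
    "SegmentationParams",
    "compute_speed_series",
    "wall_distance_series",
    "occupancy_summary",
    "segment_burst_coast",
]


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped 3-D centroid track.

    times are in s (strictly increasing, nominally uniform at interval dt);
    x, y, z are centroid coordinates in cm in the tank frame.
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    dt: float
    jitter_tol: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("times", "x", "y", "z"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.times)
        if not (len(self.x) == len(self.y) == len(self.z) == n):
            raise ValueError("times, x, y, z must have equal length")
        if n >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise ValueError("invalid time axis: times must be strictly increasing")
            if np.max(np.abs(steps - self.dt)) > max(self.jitter_tol, 1e-9 * self.dt):
                raise ValueError(
                    "invalid time axis: frame interval deviates from dt beyond tolerance"
                )
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) array of centroid positions in cm."""
        return np.column_stack([self.x, self.y, self.z])


@dataclass(frozen=True)
class SpeedSeries:
    """Component speeds and composed speed at interior trajectory samples."""

    times: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    vz: np.ndarray
    u: np.ndarray
    dt: float

    def __len__(self) -> int:
        return len(self.times)


def compute_speed_series(traj: Trajectory) -> SpeedSeries:
    """Centered two-displacement speed estimate at every interior sample.

    Raises
    ------
    ValueError
        If the trajectory has fewer than 3 samples ("insufficient
        trajectory") or a non-monotone time axis (caught at construction).
    """
    if len(traj) < 3:
        raise ValueError("insufficient trajectory: need at least 3 samples")
    two_dt = 2.0 * traj.dt

    def comp(c: np.ndarray) -> np.ndarray:
        d = np.abs(np.diff(c))
        return (d[1:] + d[:-1]) / two_dt

    vx, vy, vz = comp(traj.x), comp(traj.y), comp(traj.z)
    u = np.sqrt(vx * vx + vy * vy + vz * vz)
    return SpeedSeries(times=traj.times[1:-1], vx=vx, vy=vy, vz=vz, u=u, dt=traj.dt)


def wall_distance_series(
    traj: Trajectory,
    tank: TankGeometry,
    *,
    include_floor_surface: bool = False,
    clamp_tol_frac: float = 0.02,
) -> np.ndarray:
    """Per-sample distance (cm) to the closest tank wall.

    By default only the four vertical side walls are considered. Centroids
    slightly outside the tank (within ``clamp_tol_frac`` of the relevant
    dimension, i.e. tracking noise) are clamped to the boundary with a
    warning; samples further out raise.
    """
    x, y, z = traj.x.copy(), traj.y.copy(), traj.z.copy()
    for c, hi in ((x, tank.lx), (y, tank.ly), (z, tank.lz)):
        tol = clamp_tol_frac * hi
        bad = np.flatnonzero((c < -tol) | (c > hi + tol))
        if bad.size:
            raise ValueError(f"out-of-tank sample at index {bad[0]}")
        outside = (c < 0) | (c > hi)
        if np.any(outside):
            warnings.warn(
                f"{int(outside.sum())} centroid(s) clamped to the tank boundary",
                stacklevel=2,
            )
            np.clip(c, 0.0, hi, out=c)
    planes = [x, tank.lx - x, y, tank.ly - y]
    if include_floor_surface:
        planes += [z, tank.lz - z]
    return np.min(np.column_stack(planes), axis=1)


@dataclass(frozen=True)
class OccupancySummary:
    """Time-binned near-wall occupancy and speed summaries.

    table has one row per time bin with columns: bin_start_min, bin_end_min,
    n_samples, near_wall_fraction, mean_speed_cm_s. Histograms are
    per-bin probability-mass vectors (they sum to 1 where the bin has data).
    """

    table: pd.DataFrame
    wall_threshold_cm: float
    dist_hist_edges: np.ndarray
    dist_hists: list[np.ndarray]
    speed_hist_edges: np.ndarray
    speed_hists: list[np.ndarray]


def occupancy_summary(
    speeds: SpeedSeries,
    dists: np.ndarray,
    morph: Morphometry,
    *,
    bin_minutes: float = 30.0,
    wall_threshold_bl: float = 0.25,
    dist_hist_edges: np.ndarray | None = None,
    speed_hist_edges: np.ndarray | None = None,
) -> OccupancySummary:
    """Summarize near-wall occupancy and speed per time bin.

    dists must be aligned with ``speeds`` (same interior samples). The
    near-wall threshold is expressed in body lengths (default 0.25 BL).
    Empty bins report NaN fractions rather than zero.
    """
    dists = np.asarray(dists, dtype=float)
    if len(dists) != len(speeds):
        raise ValueError("distance series must align with the speed series")
    thr = wall_threshold_bl * morph.bl
    t0 = speeds.times[0]
    rel_min = (speeds.times - t0) / 60.0
    n_bins = max(1, int(np.ceil((rel_min[-1] + 1e-12) / bin_minutes)))
    if dist_hist_edges is None:
        dist_hist_edges = np.linspace(0.0, max(dists.max(), thr) * 1.0001, 26)
    if speed_hist_edges is None:
        speed_hist_edges = np.linspace(0.0, max(speeds.u.max(), 1e-9) * 1.0001, 26)

    rows = []
    dist_hists: list[np.ndarray] = []
    speed_hists: list[np.ndarray] = []
    for b in range(n_bins):
        lo, hi = b * bin_minutes, (b + 1) * bin_minutes
        sel = (rel_min >= lo) & (rel_min < hi)
        n = int(sel.sum())
        if n == 0:
            frac, mean_u = np.nan, np.nan
            dh = np.full(len(dist_hist_edges) - 1, np.nan)
            sh = np.full(len(speed_hist_edges) - 1, np.nan)
        else:
            frac = float(np.mean(dists[sel] < thr))
            mean_u = float(np.mean(speeds.u[sel]))
            dh = np.histogram(dists[sel], bins=dist_hist_edges)[0] / n
            sh = np.histogram(speeds.u[sel], bins=speed_hist_edges)[0] / n
        rows.append(
            dict(
                bin_start_min=lo,
                bin_end_min=hi,
                n_samples=n,
                near_wall_fraction=frac,
                mean_speed_cm_s=mean_u,
            )
        )
        dist_hists.append(dh)
        speed_hists.append(sh)
    return OccupancySummary(
        table=pd.DataFrame(rows),
        wall_threshold_cm=thr,
        dist_hist_edges=np.asarray(dist_hist_edges, float),
        dist_hists=dist_hists,
        speed_hist_edges=np.asarray(speed_hist_edges, float),
        speed_hists=speed_hists,
    )


@dataclass(frozen=True)
class BurstCoastEvent:
    """One burst-and-coast cycle: an acceleration burst then a passive glide."""

    burst_start: float
    burst_end: float
    coast_start: float
    coast_end: float
    peak_speed: float

    @property
    def burst_duration(self) -> float:
        return self.burst_end - self.burst_start

    @property
    def coast_duration(self) -> float:
        return self.coast_end - self.coast_start

    @property
    def cycle_duration(self) -> float:
        return self.coast_end - self.burst_start


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholds for burst/coast segmentation.

    smooth_window_s : centered moving-average window on the speed (s).
    accel_min : burst acceleration threshold on the smoothed speed (cm/s^2).
    speed_floor : coast end threshold (cm/s).
    min_burst_s, min_coast_s : minimum accepted durations (s).
    coast_only : if True, a leading monotone decay with no preceding burst
        is reported as a coast-only event with a zero-length burst.
    """

    smooth_window_s: float = 0.2
    accel_min: float = 2.0
    speed_floor: float = 0.2
    min_burst_s: float = 0.2
    min_coast_s: float = 0.4
    coast_only: bool = False


def _moving_average(u: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return u.astype(float)
    pad = window // 2
    padded = np.pad(u, pad, mode="edge")
    kernel = np.ones(window) / window
    out = np.convolve(padded, kernel, mode="same")[pad : pad + len(u)]
    return out


def segment_burst_coast(
    speeds: SpeedSeries, params: SegmentationParams | None = None
) -> list[BurstCoastEvent]:
    """Segment a speed series into burst-and-coast events.

    A burst is a contiguous run where the smoothed acceleration exceeds
    ``accel_min``; the following coast runs until the speed falls below
    ``speed_floor`` or the next burst begins. Events failing the minimum
    durations are discarded. An empty list is a valid outcome.
    """
    p = params or SegmentationParams()
    if len(speeds) < 3:
        return []
    dt = speeds.dt
    window = max(1, int(round(p.smooth_window_s / dt)))
    su = _moving_average(speeds.u, window)
    accel = np.gradient(su, dt)
    t = speeds.times

    in_burst = accel > p.accel_min
    # contiguous burst runs
    edges = np.flatnonzero(np.diff(in_burst.astype(int)))
    starts = [0] if in_burst[0] else []
    starts += [int(i) + 1 for i in edges if not in_burst[i]]
    ends = [int(i) + 1 for i in edges if in_burst[i]]
    if in_burst[-1]:
        ends.append(len(in_burst))
    runs = [(s, e) for s, e in zip(starts, ends) if (e - s) * dt >= p.min_burst_s]

    events: list[BurstCoastEvent] = []
    for idx, (s, e) in enumerate(runs):
        next_burst = runs[idx + 1][0] if idx + 1 < len(runs) else len(t)
        # coast: from burst end until speed floor or the next burst
        coast_end = next_burst
        below = np.flatnonzero(su[e:next_burst] < p.speed_floor)
        if below.size:
            coast_end = e + int(below[0])
        if coast_end <= e:
            continue
        if (coast_end - e) * dt < p.min_coast_s:
            continue
        events.append(
            BurstCoastEvent(
                burst_start=float(t[s]),
                burst_end=float(t[e - 1] + dt),
                coast_start=float(t[e - 1] + dt),
                coast_end=float(t[min(coast_end, len(t) - 1)]),
                peak_speed=float(np.max(speeds.u[s:coast_end])),
            )
        )
    if p.coast_only and not runs:
        su_dec = np.all(np.diff(su) <= 1e-12)
        if su_dec and (t[-1] - t[0]) >= p.min_coast_s:
            events.append(
                BurstCoastEvent(
                    burst_start=float(t[0]),
                    burst_end=float(t[0]),
                    coast_start=float(t[0]),
                    coast_end=float(t[-1]),
                    peak_speed=float(speeds.u[0]),
                )
            )
    return events
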