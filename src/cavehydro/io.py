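"""Readers and writers for the package's plain-text interchange formats.

All tabular artifacts are CSV with `#` comment lines and documented
headers; numeric output is written with `repr` precision so values
round-trip losslessly. Coordinate convention for trajectories: x along
the tank length, y across the width, z vertical up, origin at a bottom
corner of the water volume.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .drag import CoastingSequence, DragFitResult
from .flow import BodyContour, PanelSolution, PoreChain
from .kinematics import BurstCoastEvent, Trajectory

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "read_coasting_sequence",
    "write_coasting_sequence",
    "read_contour",
    "write_contour",
    "read_velocity_frame",
    "read_frame_manifest",
    "write_velocity_frame",
    "write_frame_manifest",
    "write_events",
    "write_drag_fits",
    "write_panel_solution",
    "write_pore_chain",
    "write_json",
]

_FLOAT_FMT = "%.12g"


def read_trajectory(path, dt: float | None = None) -> Trajectory:
    """Read a `t_s,x_cm,y_cm,z_cm` trajectory CSV.

    dt defaults to the median frame interval of the file.
    """
    df = pd.read_csv(path, comment="#")
    required = ["t_s", "x_cm", "y_cm", "z_cm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    t = df["t_s"].to_numpy(float)
    if dt is None:
        if len(t) < 2:
            raise ValueError(f"{path}: cannot infer dt from fewer than 2 rows")
        dt = float(np.median(np.diff(t)))
    return Trajectory(
        times=t,
        x=df["x_cm"].to_numpy(float),
        y=df["y_cm"].to_numpy(float),
        z=df["z_cm"].to_numpy(float),
        dt=dt,
    )


def write_trajectory(path, traj: Trajectory) -> None:
    df = pd.DataFrame(
        {"t_s": traj.times, "x_cm": traj.x, "y_cm": traj.y, "z_cm": traj.z}
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_coasting_sequence(path) -> CoastingSequence:
    """Read a `t_s,u_cm_per_s` coasting-glide CSV."""
    df = pd.read_csv(path, comment="#")
    for c in ("t_s", "u_cm_per_s"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c}")
    return CoastingSequence(
        times=df["t_s"].to_numpy(float),
        u=df["u_cm_per_s"].to_numpy(float),
        label=Path(path).stem,
    )


def write_coasting_sequence(path, seq: CoastingSequence) -> None:
    pd.DataFrame({"t_s": seq.times, "u_cm_per_s": seq.u}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_contour(path, label: str | None = None) -> BodyContour:
    """Read a closed `s_bl,x_bl,z_bl` polyline CSV."""
    df = pd.read_csv(path, comment="#")
    for c in ("x_bl", "z_bl"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c}")
    return BodyContour(
        vertices=df[["x_bl", "z_bl"]].to_numpy(float),
        label=label if label is not None else Path(path).stem,
    )


def write_contour(path, contour: BodyContour) -> None:
    v = contour.vertices
    seg = np.linalg.norm(np.diff(v, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    pd.DataFrame({"s_bl": s, "x_bl": v[:, 0], "z_bl": v[:, 1]}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_velocity_frame(path, time: float = 0.0, h: float = 0.002):
    """Read one `y_m,z_m,vy_m_per_s,vz_m_per_s` gridded frame file.

    Rows must cover a complete rectangular grid (any order).
    """
    from .piv import VelocityFrame

    df = pd.read_csv(path, comment="#")
    for c in ("y_m", "z_m", "vy_m_per_s", "vz_m_per_s"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c}")
    y = np.unique(df["y_m"].to_numpy(float))
    z = np.unique(df["z_m"].to_numpy(float))
    if len(df) != len(y) * len(z):
        raise ValueError(f"{path}: rows do not form a complete {len(y)}x{len(z)} grid")
    piv = df.pivot_table(index="y_m", columns="z_m")
    vy = piv["vy_m_per_s"].to_numpy(float)
    vz = piv["vz_m_per_s"].to_numpy(float)
    return VelocityFrame(time=time, y=y, z=z, vy=vy, vz=vz, h=h)


def write_velocity_frame(path, frame) -> None:
    yy, zz = np.meshgrid(frame.y, frame.z, indexing="ij")
    pd.DataFrame(
        {
            "y_m": yy.ravel(),
            "z_m": zz.ravel(),
            "vy_m_per_s": frame.vy.ravel(),
            "vz_m_per_s": frame.vz.ravel(),
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_frame_manifest(path, h: float = 0.002):
    """Read a `frame,file,t_s` manifest and its referenced frame files.

    File paths are resolved relative to the manifest's directory.
    """
    base = Path(path).parent
    df = pd.read_csv(path, comment="#")
    for c in ("frame", "file", "t_s"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c}")
    df = df.sort_values("frame")
    return [
        read_velocity_frame(base / row.file, time=float(row.t_s), h=h)
        for row in df.itertuples()
    ]


def write_frame_manifest(directory, frames, prefix: str = "frame") -> Path:
    """Write frames plus a manifest CSV into ``directory``; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, f in enumerate(frames):
        name = f"{prefix}_{i:04d}.csv"
        write_velocity_frame(directory / name, f)
        rows.append(dict(frame=i, file=name, t_s=f.time))
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False, float_format=_FLOAT_FMT)
    return manifest


def write_events(path, events: list[BurstCoastEvent]) -> None:
    pd.DataFrame(
        [
            dict(
                burst_start_s=e.burst_start,
                burst_end_s=e.burst_end,
                coast_start_s=e.coast_start,
                coast_end_s=e.coast_end,
                burst_s=e.burst_duration,
                coast_s=e.coast_duration,
                cycle_s=e.cycle_duration,
                peak_speed_cm_s=e.peak_speed,
            )
            for e in events
        ]
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_drag_fits(path, fits: list[DragFitResult]) -> None:
    pd.DataFrame(
        [
            dict(
                label=f.label,
                cd_coast=f.cd_coast,
                slope_per_cm=f.slope_per_cm,
                intercept_s_per_cm=f.intercept_s_per_cm,
                r_squared=f.r_squared,
                effective_mass_g=f.effective_mass_g,
                k=f.k,
                valid=f.valid,
            )
            for f in fits
        ]
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_panel_solution(path, sol: PanelSolution) -> None:
    v = sol.contour.vertices
    seg = np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1)
    s_mid = np.cumsum(seg) - seg / 2
    pd.DataFrame(
        {
            "s_bl": s_mid,
            "x_bl": sol.midpoints[:, 0],
            "z_bl": sol.midpoints[:, 1],
            "cp": sol.cp,
            "P_pa": sol.pressure,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_pore_chain(path, chain: PoreChain) -> None:
    delta = np.concatenate([chain.delta_cp, [np.nan]])
    pd.DataFrame(
        {
            "pore_index": np.arange(len(chain)),
            "s_bl": chain.s,
            "cp": chain.cp,
            "delta_cp": delta,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
        fh.write("\n")
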