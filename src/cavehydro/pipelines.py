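"""End-to-end orchestration of the two laboratory analyses and the flow study.

Experiment 1: free-swimming behavior — trajectory → speed series, wall
distances, time-binned occupancy/speed summaries.

Experiment 2: coasting drag fits over a batch of glides, plus the
PIV-plane sensing-distance detection over approach sequences.

Flow study: panel-method surface pressure on streamlined and horned
contours, pore placement, ΔCp stimulus profiles and pressure-drag
integration.

Each runner accepts real inputs or, with ``simulate=True``, generates
synthetic ones from the configured seed, writes all artifacts into the
output directory, and emits a RunReport.
"""

from __future__ import annotations

import time
from pathlib import Path

import numpy as np

from . import io as chio
from .config import RunConfig, RunReport
from .drag import fit_drag_coefficient
from .flow import FreeStream, delta_cp_profile, integrate_drag, place_pores, solve_panel_flow
from .kinematics import (
    SegmentationParams,
    compute_speed_series,
    occupancy_summary,
    segment_burst_coast,
    wall_distance_series,
)
from .piv import DetectionParams, detect_sensing_event
from .synth import (
    ContourGenParams,
    PIVGenParams,
    TrajectoryGenParams,
    gen_contour,
    gen_coasting_batch,
    gen_piv_sequence,
    gen_trajectory,
)

__all__ = ["run_experiment1", "run_experiment2", "run_flow_study"]


def _prep(config: RunConfig, out_dir) -> Path:
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_experiment1(
    config: RunConfig,
    trajectory=None,
    *,
    simulate: bool = False,
    gen_params: TrajectoryGenParams | None = None,
    out_dir=None,
):
    """Behavior summary: occupancy, speeds, burst/coast events.

    ``trajectory`` is a Trajectory or a path to a trajectory CSV; with
    ``simulate=True`` a session is generated instead. Returns
    (OccupancySummary, events, RunReport).
    """
    t0 = time.perf_counter()
    out = _prep(config, out_dir)
    morph = config.morphometry.build()
    tank = config.tank.build()
    thr = config.thresholds

    if simulate:
        params = gen_params or TrajectoryGenParams(
            tank=tank,
            morph=morph,
            wall_threshold_bl=thr.wall_threshold_bl,
            seed=config.seed,
        )
        traj, truth = gen_trajectory(params)
        chio.write_trajectory(out / "trajectory.csv", traj)
        chio.write_json(out / "trajectory_truth.json", truth.__dict__)
    elif trajectory is None:
        raise ValueError("experiment1: provide a trajectory or pass simulate=True")
    elif isinstance(trajectory, (str, Path)):
        traj = chio.read_trajectory(trajectory)
    else:
        traj = trajectory

    speeds = compute_speed_series(traj)
    dists = wall_distance_series(traj, tank)[1:-1]
    summary = occupancy_summary(
        speeds,
        dists,
        morph,
        bin_minutes=thr.bin_minutes,
        wall_threshold_bl=thr.wall_threshold_bl,
    )
    events = segment_burst_coast(
        speeds,
        SegmentationParams(
            smooth_window_s=thr.smooth_window_s,
            accel_min=thr.accel_min_cm_s2,
            speed_floor=thr.u_floor_cm_s,
            min_burst_s=thr.min_burst_s,
            min_coast_s=thr.min_coast_s,
        ),
    )
    summary.table.to_csv(out / "occupancy_summary.csv", index=False)
    chio.write_events(out / "burst_coast_events.csv", events)
    report = RunReport(
        stage="experiment1",
        config_hash=config.config_hash(),
        seed=config.seed,
        inputs={"trajectory_samples": len(traj)},
        outputs={"bins": len(summary.table), "events": len(events)},
        warnings=config.warnings(),
        elapsed_s=time.perf_counter() - t0,
    )
    report.write(out / "report_experiment1.json")
    return summary, events, report


def run_experiment2(
    config: RunConfig,
    coasting_sequences=None,
    frame_sequences=None,
    *,
    simulate: bool = False,
    n_coasts: int = 65,
    n_approaches: int = 21,
    out_dir=None,
):
    """Drag-coefficient fits plus sensing-distance detection.

    Returns (list of DragFitResult, list of SensingEvent-or-None, RunReport).
    """
    t0 = time.perf_counter()
    out = _prep(config, out_dir)
    morph = config.morphometry.build()
    fluid = config.fluid.build()
    rng = np.random.default_rng(config.seed)

    if simulate:
        coasting_sequences, truth = gen_coasting_batch(
            n_coasts, 0.09, morph, fluid, k=config.added_mass_k, seed=config.seed
        )
        chio.write_json(out / "coasting_truth.json", truth)
        frame_sequences = []
        for i in range(n_approaches):
            seq, _ = gen_piv_sequence(
                PIVGenParams(
                    morph=morph,
                    approach_speed_cm_s=float(rng.uniform(1.0, 10.0)),
                    seed=config.seed * 10_000 + i,
                )
            )
            frame_sequences.append(seq)
    if coasting_sequences is None and frame_sequences is None:
        raise ValueError("experiment2: provide inputs or pass simulate=True")

    fits = []
    for seq in coasting_sequences or []:
        fits.append(
            fit_drag_coefficient(
                seq,
                morph,
                fluid,
                k=config.added_mass_k,
                u_floor=config.thresholds.u_floor_cm_s,
            )
        )
    chio.write_drag_fits(out / "drag_fits.csv", fits)

    events = []
    det = DetectionParams(z=config.thresholds.sensing_z)
    for seq in frame_sequences or []:
        events.append(detect_sensing_event(seq, fluid, det))
    chio.write_json(
        out / "sensing_events.json",
        [
            None
            if e is None
            else dict(d_l_bl=e.d_l_bl, u_l_cm_s=e.u_l_cm_s, onset_time=e.onset_time)
            for e in events
        ],
    )
    report = RunReport(
        stage="experiment2",
        config_hash=config.config_hash(),
        seed=config.seed,
        inputs={
            "coasting_sequences": len(coasting_sequences or []),
            "frame_sequences": len(frame_sequences or []),
        },
        outputs={
            "drag_fits": len(fits),
            "sensing_events": sum(e is not None for e in events),
        },
        warnings=config.warnings(),
        elapsed_s=time.perf_counter() - t0,
    )
    report.write(out / "report_experiment2.json")
    return fits, events, report


def run_flow_study(
    config: RunConfig,
    contours=None,
    *,
    u_inflow_m_s: float = 0.0157,
    n_panels: int = 240,
    pore_spacing_bl: float = 0.02,
    out_dir=None,
):
    """Panel-flow pressure, pore ΔCp profiles and drag for a set of contours.

    With no contours given, a streamlined and a horned contour are
    generated. Returns (dict label → (solution, chain, drag), RunReport).
    """
    t0 = time.perf_counter()
    out = _prep(config, out_dir)
    fluid = config.fluid.build()
    stream = FreeStream(u=u_inflow_m_s, fluid=fluid)
    if contours is None:
        contours = [
            gen_contour(ContourGenParams(family="streamlined", n_vertices=n_panels)),
            gen_contour(ContourGenParams(family="horned", n_vertices=n_panels)),
        ]
    results = {}
    for contour in contours:
        sol = solve_panel_flow(contour, stream)
        chain = place_pores(contour, sol, spacing=pore_spacing_bl)
        height = contour.vertices[:, 1].max() - contour.vertices[:, 1].min()
        drag = integrate_drag(sol, contour, stream, reference_area=height)
        label = contour.label or f"contour_{len(results)}"
        chio.write_panel_solution(out / f"panels_{label}.csv", sol)
        chio.write_pore_chain(out / f"pores_{label}.csv", chain)
        delta_cp_profile(chain).to_csv(out / f"delta_cp_{label}.csv", index=False)
        chio.write_json(
            out / f"drag_{label}.json",
            dict(
                force_per_span=drag.force,
                cd=drag.cd,
                reference_area=drag.reference_area,
                per_unit_span=drag.per_unit_span,
            ),
        )
        results[label] = (sol, chain, drag)
    report = RunReport(
        stage="flow_study",
        config_hash=config.config_hash(),
        seed=config.seed,
        inputs={"contours": len(contours)},
        outputs={"solutions": len(results)},
        warnings=config.warnings(),
        elapsed_s=time.perf_counter() - t0,
    )
    report.write(out / "report_flow_study.json")
    return results, report
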