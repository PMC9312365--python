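"""Surface pressure and lateral-line stimulus around 2-D body contours.

A constant-strength source-panel method (potential flow, no circulation)
provides a desk-scale surrogate for volume-resolved CFD: it yields the
tangential surface velocity, the pressure coefficient

    Cp = P / ((ρ/2) U^2) = 1 - (v_t / U)^2,

and the gauge surface pressure for head-on onset flow around a closed
contour. Canal pores are placed every 2% of body length along the dorsal
path from the snout, and the difference in Cp between adjacent pores
(ΔCp) quantifies the stimulus to a canal neuromast sitting between them.

Pressure drag follows from integrating the surface pressure over the
upstream-facing projection of the body. For a smooth closed body in ideal
flow this integral vanishes with panel refinement (d'Alembert), which is
the solver's built-in oracle; drag from *imported* (e.g. RANS) pressure
fields is genuinely nonzero and is post-processed by the same routine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import FluidProperties

__all__ = [
    "BodyContour",
    "FreeStream",
    "PanelSolution",
    "PoreChain",
    "DragResult",
    "SurfacePressure",
    "solve_panel_flow",
    "pressure_from_cp",
    "cp_from_pressure",
    "integrate_drag",
    "place_pores",
    "delta_cp_profile",
    "import_surface_pressure",
    "write_surface_pressure",
]


def _polygon_area(v: np.ndarray) -> float:
    x, z = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(z, -1) - np.roll(x, -1) * z))


@dataclass(frozen=True)
class BodyContour:
    """Closed 2-D body outline in BL-normalized units, snout near the origin.

    vertices : (N, 2) array of (x, z) points, x anterior → posterior,
    z ventral → dorsal. The closing edge from the last vertex back to the
    first is implicit. Orientation is normalized to counterclockwise.
    """

    vertices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("vertices must be an (N, 2) array")
        if np.allclose(v[0], v[-1]):
            v = v[:-1]
        if len(v) < 3:
            raise ValueError("contour needs at least 3 distinct vertices")
        if _polygon_area(v) < 0:
            v = v[::-1].copy()
        seg = np.linalg.norm(np.diff(np.vstack([v, v[:1]]), axis=0), axis=1)
        if np.any(seg < 1e-12):
            raise ValueError("degenerate contour: duplicated adjacent vertices")
        try:
            from shapely.geometry import Polygon

            if not Polygon(v).is_simple:
                raise ValueError("contour is self-intersecting")
        except ImportError:  # pragma: no cover - shapely is a soft check
            pass
        object.__setattr__(self, "vertices", v)
        if len(v) < 60:
            warnings.warn(
                f"contour has {len(v)} vertices; >= 60 recommended for the panel solver",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def segment_lengths(self) -> np.ndarray:
        v = self.vertices
        return np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1)

    @property
    def perimeter(self) -> float:
        return float(self.segment_lengths.sum())


@dataclass(frozen=True)
class FreeStream:
    """Head-on onset flow along +x."""

    u: float
    fluid: FluidProperties

    def __post_init__(self) -> None:
        if self.u <= 0:
            raise ValueError("free-stream speed must be positive")

    @property
    def dynamic_pressure(self) -> float:
        """(ρ/2) U^2 in Pa when u is m/s and fluid density kg/m^3."""
        return 0.5 * self.fluid.density * self.u**2


@dataclass(frozen=True)
class PanelSolution:
    """Per-panel surface solution of the source-panel method."""

    contour: BodyContour
    midpoints: np.ndarray
    tangents: np.ndarray
    normals: np.ndarray
    lengths: np.ndarray
    source_strengths: np.ndarray
    v_tangential: np.ndarray
    cp: np.ndarray
    pressure: np.ndarray
    stream: FreeStream


def _panel_geometry(contour: BodyContour):
    v = contour.vertices
    a = v
    b = np.roll(v, -1, axis=0)
    d = b - a
    lengths = np.linalg.norm(d, axis=1)
    tangents = d / lengths[:, None]
    # CCW polygon: outward normal is the right-hand rotation of the tangent
    normals = np.column_stack([tangents[:, 1], -tangents[:, 0]])
    midpoints = 0.5 * (a + b)
    return a, midpoints, tangents, normals, lengths


def solve_panel_flow(contour: BodyContour, stream: FreeStream) -> PanelSolution:
    """Solve head-on potential flow with constant-strength source panels.

    Collocation at panel midpoints enforces zero normal velocity; the
    resulting tangential velocities give Cp = 1 - (v_t/U)^2 and the gauge
    pressure P = Cp (ρ/2) U^2. Non-lifting: circulation is identically zero.
    """
    a, mid, tau, nu, lengths = _panel_geometry(contour)
    n = len(lengths)

    # local coordinates of every collocation point in every panel frame
    rel = mid[:, None, :] - a[None, :, :]  # (i, j, 2)
    xi = np.einsum("ijk,jk->ij", rel, tau)
    eta = np.einsum("ijk,jk->ij", rel, nu)
    r1sq = xi**2 + eta**2
    xl = xi - lengths[None, :]
    r2sq = xl**2 + eta**2
    with np.errstate(divide="ignore", invalid="ignore"):
        u_xi = np.log(r1sq / r2sq) / (4 * np.pi)
    u_eta = (np.arctan2(eta, xl) - np.arctan2(eta, xi)) / (2 * np.pi)
    diag = np.eye(n, dtype=bool)
    u_xi[diag] = 0.0
    u_eta[diag] = 0.5

    # back to global components, then project on collocation normals/tangents
    ux = u_xi * tau[None, :, 0] + u_eta * nu[None, :, 0]
    uz = u_xi * tau[None, :, 1] + u_eta * nu[None, :, 1]
    a_mat = ux * nu[:, 0][:, None] + uz * nu[:, 1][:, None]
    t_mat = ux * tau[:, 0][:, None] + uz * tau[:, 1][:, None]

    u_inf = np.array([stream.u, 0.0])
    rhs = -(nu @ u_inf)
    try:
        sigma = np.linalg.solve(a_mat, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular panel system (degenerate contour?)") from exc

    v_t = tau @ u_inf + t_mat @ sigma
    cp = 1.0 - (v_t / stream.u) ** 2
    pressure = pressure_from_cp(cp, stream)
    return PanelSolution(
        contour=contour,
        midpoints=mid,
        tangents=tau,
        normals=nu,
        lengths=lengths,
        source_strengths=sigma,
        v_tangential=v_t,
        cp=cp,
        pressure=pressure,
        stream=stream,
    )


def pressure_from_cp(cp: np.ndarray | float, stream: FreeStream) -> np.ndarray | float:
    """Gauge pressure P = Cp (ρ/2) U^2 (Pa)."""
    return np.asarray(cp, float) * stream.dynamic_pressure if np.ndim(cp) else cp * stream.dynamic_pressure


def cp_from_pressure(pressure: np.ndarray | float, stream: FreeStream) -> np.ndarray | float:
    """Exact inverse of :func:`pressure_from_cp`."""
    q = stream.dynamic_pressure
    if q == 0:
        raise ValueError("free-stream dynamic pressure is zero")
    return np.asarray(pressure, float) / q if np.ndim(pressure) else pressure / q


@dataclass(frozen=True)
class DragResult:
    """Pressure drag and its coefficient Cd = F / ((ρ/2) A U^2)."""

    force: float
    cd: float
    reference_area: float
    per_unit_span: bool


@dataclass(frozen=True)
class SurfacePressure:
    """Arc-length-ordered surface pressure samples bound to a named contour.

    s is the contour arc-length coordinate (BL), pressure in Pa (gauge).
    """

    s: np.ndarray
    pressure: np.ndarray
    contour_label: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.s, float)
        p = np.asarray(self.pressure, float)
        if len(s) != len(p):
            raise ValueError("s and pressure must have equal length")
        if len(s) == 0:
            raise ValueError("empty surface-pressure record")
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "pressure", p)


def _panel_pressures(
    pressures: PanelSolution | SurfacePressure | np.ndarray,
    contour: BodyContour,
) -> np.ndarray:
    if isinstance(pressures, PanelSolution):
        return pressures.pressure
    lengths = contour.segment_lengths
    if isinstance(pressures, SurfacePressure):
        s_mid = np.cumsum(lengths) - lengths / 2
        return np.interp(s_mid, pressures.s, pressures.pressure)
    arr = np.asarray(pressures, float)
    if len(arr) != len(lengths):
        raise ValueError("per-panel pressure array does not match panel count")
    return arr


def integrate_drag(
    pressures: PanelSolution | SurfacePressure | np.ndarray,
    contour: BodyContour,
    stream: FreeStream,
    reference_area: float,
    *,
    per_unit_span: bool = True,
) -> DragResult:
    """Integrate surface pressure into streamwise drag.

    F = -Σ P_i (n_i · x̂) L_i per unit span: pressure on upstream-facing
    panels (outward normal against the flow) pushes the body downstream and
    counts as positive drag. A uniform pressure over a closed contour gives
    exactly zero. ``reference_area`` normalizes Cd (projected frontal
    length per unit span for intrinsic 2-D results; specimen surface area
    for imported 3-D fields).
    """
    _, _, _, normals, lengths = _panel_geometry(contour)
    p = _panel_pressures(pressures, contour)
    force = float(-np.sum(p * normals[:, 0] * lengths))
    cd = force / (stream.dynamic_pressure * reference_area)
    return DragResult(
        force=force, cd=cd, reference_area=reference_area, per_unit_span=per_unit_span
    )


@dataclass(frozen=True)
class PoreChain:
    """Canal pores along the dorsal path at fixed arc-length spacing.

    s is the distance from the snout along the body surface (BL); cp the
    interpolated pressure coefficient at each pore.
    """

    s: np.ndarray
    cp: np.ndarray
    spacing: float
    head_region_bl: float = 0.3

    def __len__(self) -> int:
        return len(self.s)

    @property
    def delta_cp(self) -> np.ndarray:
        """ΔCp_i = Cp_{i+1} - Cp_i between adjacent pores."""
        return np.diff(self.cp)

    @property
    def head_mask(self) -> np.ndarray:
        """Pores within the head region (s <= 0.3 BL by default)."""
        return self.s <= self.head_region_bl


def _dorsal_path(contour: BodyContour) -> tuple[np.ndarray, np.ndarray]:
    """Vertex sequence from snout to tail over the dorsal side.

    Returns (path_points, panel_indices) where panel_indices[k] is the
    panel traversed between path point k and k+1.
    """
    v = contour.vertices
    n = len(v)
    i_snout = int(np.argmin(v[:, 0]))
    i_tail = int(np.argmax(v[:, 0]))

    def walk(direction: int) -> list[int]:
        seq = [i_snout]
        i = i_snout
        while i != i_tail:
            i = (i + direction) % n
            seq.append(i)
        return seq

    fwd, bwd = walk(+1), walk(-1)
    z_fwd = np.mean(v[fwd, 1])
    z_bwd = np.mean(v[bwd, 1])
    seq = fwd if z_fwd >= z_bwd else bwd
    direction = +1 if seq is fwd else -1
    pts = v[seq]
    # panel between vertex i and i+1 has index i
    panels = []
    for k in range(len(seq) - 1):
        i = seq[k]
        panels.append(i if direction == +1 else (i - 1) % n)
    return pts, np.asarray(panels, int)


def place_pores(
    contour: BodyContour,
    solution: PanelSolution | None = None,
    spacing: float = 0.02,
    *,
    cp: np.ndarray | None = None,
) -> PoreChain:
    """Place canal pores every ``spacing`` BL along the dorsal path.

    The path runs from the snout (anterior-most vertex) over the dorsal
    surface to the tail. Cp at each pore is linearly interpolated in arc
    length between panel-midpoint values, taken from ``solution`` or from
    an explicit per-panel ``cp`` array.
    """
    if spacing <= 0:
        raise ValueError("pore spacing must be positive")
    pts, panel_idx = _dorsal_path(contour)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total < spacing:
        raise ValueError("contour dorsal path shorter than the pore spacing")
    s_pores = np.arange(0.0, total + 1e-12, spacing)
    s_pores = s_pores[s_pores <= total]

    if cp is None:
        if solution is None:
            raise ValueError("provide a PanelSolution or a per-panel cp array")
        cp = solution.cp
    cp = np.asarray(cp, float)
    s_mid = 0.5 * (cum[:-1] + cum[1:])
    cp_mid = cp[panel_idx]
    cp_pores = np.interp(s_pores, s_mid, cp_mid)
    return PoreChain(s=s_pores, cp=cp_pores, spacing=spacing)


def delta_cp_profile(chain: PoreChain):
    """ΔCp between adjacent pores against arc distance from the snout.

    Returns a tidy DataFrame with the midpoint arc position of each
    adjacent-pore pair, the ΔCp stimulus, and a head-region flag.
    """
    import pandas as pd

    if len(chain) < 2:
        raise ValueError("need at least two pores")
    s_mid = 0.5 * (chain.s[:-1] + chain.s[1:])
    return pd.DataFrame(
        {
            "s_bl": s_mid,
            "delta_cp": chain.delta_cp,
            "head_region": s_mid <= chain.head_region_bl,
        }
    )


def import_surface_pressure(path, contour_label: str = "") -> SurfacePressure:
    """Read `s_bl,P_pa` CSV samples; out-of-order rows are sorted with a warning.

    Schema violations are reported with their line number.
    """
    s_vals: list[float] = []
    p_vals: list[float] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.lower().replace(" ", "") == "s_bl,p_pa":
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected two comma-separated fields")
            try:
                s_vals.append(float(parts[0]))
                p_vals.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-numeric field") from exc
    if not s_vals:
        raise ValueError(f"{path}: no surface-pressure samples found")
    s = np.asarray(s_vals)
    p = np.asarray(p_vals)
    if np.any(np.diff(s) < 0):
        warnings.warn(f"{path}: samples out of arc-length order; sorting", stacklevel=2)
        order = np.argsort(s, kind="stable")
        s, p = s[order], p[order]
    return SurfacePressure(s=s, pressure=p, contour_label=contour_label)


def write_surface_pressure(path, sp: SurfacePressure) -> None:
    """Write `s_bl,P_pa` CSV at full double precision."""
    with open(path, "w") as fh:
        fh.write("s_bl,P_pa\n")
        for s, p in zip(sp.s, sp.pressure):
            fh.write(f"{float(s)!r},{float(p)!r}\n")
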