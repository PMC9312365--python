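"""Coasting drag-coefficient inference from glide deceleration.

During a coast the fish glides with a straight body and decelerates under
quadratic (form) drag. With effective inertia m_eff = M + k ρ V (the
added-mass coefficient k accounts for entrained water), Newton's law

    m_eff du/dt = -(1/2) Cd ρ A u^2

integrates in closed form to

    u(t) = u0 / (1 + β u0 t),      β = Cd ρ A / (2 m_eff),

equivalently a *linear* reciprocal-speed law 1/u(t) = β t + 1/u0. The drag
coefficient is therefore recovered by ordinary least squares of 1/u on t:

    Cd = slope · 2 (M + k ρ V) / (ρ A).

The fit is carried out in cm-g-s units (ρ in g/cm^3, u in cm/s), so the
slope has units 1/cm; Cd is dimensionless and unit-system invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import FluidProperties, Morphometry

__all__ = [
    "CoastingSequence",
    "DragFitResult",
    "ReynoldsResult",
    "coasting_beta",
    "simulate_coasting",
    "fit_drag_coefficient",
    "reynolds_number",
    "DEFAULT_ADDED_MASS_K",
]

#: Default added-mass coefficient. The study's running text sets k = 0.045
#: (with literature support); its symbol table prints 0.45. The text value
#: is the default; pass k explicitly to override.
DEFAULT_ADDED_MASS_K = 0.045


@dataclass(frozen=True)
class CoastingSequence:
    """Speed record of a single coasting glide: times (s), speeds u (cm/s)."""

    times: np.ndarray
    u: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, float))
        object.__setattr__(self, "u", np.asarray(self.u, float))
        if len(self.times) != len(self.u):
            raise ValueError("times and u must have equal length")
        if len(self.times) >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class DragFitResult:
    """Result of the reciprocal-speed linear fit."""

    cd_coast: float
    slope_per_cm: float
    intercept_s_per_cm: float
    r_squared: float
    effective_mass_g: float
    k: float
    valid: bool
    label: str = ""


@dataclass(frozen=True)
class ReynoldsResult:
    re: float
    u_m_s: float
    length_m: float
    nu_m2_s: float


def _effective_mass_g(morph: Morphometry, fluid: FluidProperties, k: float) -> float:
    return morph.mass + k * fluid.density_cgs * morph.volume


def coasting_beta(
    cd: float, morph: Morphometry, fluid: FluidProperties, k: float = DEFAULT_ADDED_MASS_K
) -> float:
    """Decay constant β = Cd ρ A / (2 (M + k ρ V)) in 1/cm (cgs units)."""
    return cd * fluid.density_cgs * morph.area / (2.0 * _effective_mass_g(morph, fluid, k))


def simulate_coasting(
    u0: float,
    cd: float,
    morph: Morphometry,
    fluid: FluidProperties,
    *,
    k: float = DEFAULT_ADDED_MASS_K,
    duration: float = 2.0,
    rate: float = 10.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    label: str = "",
) -> CoastingSequence:
    """Closed-form quadratic-drag glide u(t) = u0 / (1 + β u0 t).

    u0 is the initial speed (cm/s), rate the sampling rate (Hz).
    Multiplicative Gaussian noise of standard deviation ``noise_sd`` is
    applied per sample when nonzero (requires ``rng``). Cd = 0 yields a
    constant-speed glide.
    """
    if u0 <= 0:
        raise ValueError("u0 must be positive")
    if cd < 0:
        raise ValueError("cd must be non-negative")
    t = np.arange(0.0, duration + 0.5 / rate, 1.0 / rate)
    beta = coasting_beta(cd, morph, fluid, k)
    u = u0 / (1.0 + beta * u0 * t)
    if noise_sd > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        u = u * (1.0 + noise_sd * gen.standard_normal(len(t)))
        u = np.clip(u, 1e-6, None)
    return CoastingSequence(times=t, u=u, label=label)


def fit_drag_coefficient(
    seq: CoastingSequence,
    morph: Morphometry,
    fluid: FluidProperties,
    *,
    k: float = DEFAULT_ADDED_MASS_K,
    u_floor: float = 0.2,
    weighted: bool = False,
    units: str = "cgs",
) -> DragFitResult:
    """Fit Cd from the linear decay of reciprocal speed.

    Samples below ``u_floor`` (cm/s) are trimmed from the tail (1/u
    amplifies noise at low speed). A non-positive slope flags the result
    invalid rather than returning a spurious Cd.

    ``units`` selects the consistent unit system of the inputs: "cgs"
    (u in cm/s, morphometry in cm/g — the default laboratory convention)
    or "si" (u in m/s, morphometry fields carrying m/kg values). Cd is
    dimensionless and identical either way.
    """
    t, u = seq.times, seq.u
    keep = u > u_floor
    # trim only a trailing run of sub-floor samples
    if not keep.all():
        last = np.flatnonzero(keep)
        if last.size == 0:
            raise ValueError("all speeds below the floor")
        t, u = t[: last[-1] + 1], u[: last[-1] + 1]
    if len(t) < 4:
        raise ValueError("need at least 4 points above the speed floor")
    y = 1.0 / u
    if weighted:
        w = u**2  # reciprocal-variance weights for multiplicative speed noise
        slope, intercept = np.polyfit(t, y, 1, w=np.sqrt(w))
        yhat = slope * t + intercept
        ss_res = np.sum(w * (y - yhat) ** 2)
        ss_tot = np.sum(w * (y - np.average(y, weights=w)) ** 2)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    else:
        res = stats.linregress(t, y)
        slope, intercept = res.slope, res.intercept
        r2 = res.rvalue**2
    if units == "cgs":
        rho = fluid.density_cgs
    elif units == "si":
        rho = fluid.density
    else:
        raise ValueError("units must be 'cgs' or 'si'")
    m_eff = morph.mass + k * rho * morph.volume
    cd = slope * 2.0 * m_eff / (rho * morph.area)
    return DragFitResult(
        cd_coast=float(cd),
        slope_per_cm=float(slope),
        intercept_s_per_cm=float(intercept),
        r_squared=float(r2),
        effective_mass_g=float(m_eff),
        k=k,
        valid=bool(slope > 0),
        label=seq.label,
    )


def reynolds_number(u: float, length: float, fluid: FluidProperties) -> ReynoldsResult:
    """Re = u L / ν with u in m/s and L in m."""
    if u <= 0 or length <= 0:
        raise ValueError("speed and length must be positive")
    return ReynoldsResult(
        re=u * length / fluid.kinematic_viscosity,
        u_m_s=u,
        length_m=length,
        nu_m2_s=fluid.kinematic_viscosity,
    )
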