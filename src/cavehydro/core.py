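"""Shared domain types: specimen morphometry, tank geometry, fluid properties.

Units follow the laboratory convention used throughout the package:
lengths in cm, areas in cm^2, volumes in cm^3, mass in g, time in s,
speeds in cm/s — except where a function explicitly documents SI units
(PIV fields and panel-method free streams are in metres and m/s).

Coordinate convention for trajectories: x along the tank length, y across
the width, z vertical up, origin at a bottom corner of the water volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

__all__ = ["Morphometry", "TankGeometry", "FluidProperties"]


@dataclass(frozen=True)
class Morphometry:
    """Specimen body measurements.

    Defaults are the study specimen: a blind troglobite cavefish of body
    length 8.6 cm.

    Attributes
    ----------
    bl : float
        Body length BL (cm).
    bh : float
        Body height BH (cm).
    bw : float
        Body width BW (cm).
    area : float
        Body surface area A (cm^2).
    volume : float
        Body volume V (cm^3).
    mass : float
        Body mass M (g).
    """

    bl: float = 8.6
    bh: float = 2.2
    bw: float = 1.1
    area: float = 36.6
    volume: float = 4.4
    mass: float = 4.84

    def __post_init__(self) -> None:
        for name in ("bl", "bh", "bw", "area", "volume", "mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"Morphometry.{name} must be strictly positive")
        if not (self.bl > self.bh > self.bw):
            warnings.warn(
                "expected fish-like proportions BL > BH > BW; got "
                f"BL={self.bl}, BH={self.bh}, BW={self.bw}",
                stacklevel=2,
            )


@dataclass(frozen=True)
class TankGeometry:
    """Rectangular water volume (cm), corner at the origin.

    x spans [0, lx) along the length, y spans [0, ly) across the width and
    z spans [0, lz) vertically.
    """

    lx: float = 40.0
    ly: float = 25.0
    lz: float = 8.0

    def __post_init__(self) -> None:
        if min(self.lx, self.ly, self.lz) <= 0:
            raise ValueError("tank dimensions must be positive")

    def contains(self, x: float, y: float, z: float) -> bool:
        return 0 <= x < self.lx and 0 <= y < self.ly and 0 <= z < self.lz


@dataclass(frozen=True)
class FluidProperties:
    """Water properties at the experimental temperature (17 °C).

    density is in kg/m^3 (991 by default, the study's tabulated value;
    pure water at 17 °C is closer to 998.8 — the tabulated value is kept so
    the drag arithmetic reproduces the study's numbers) and
    kinematic_viscosity in m^2/s.
    """

    density: float = 991.0
    kinematic_viscosity: float = 1.085e-6

    def __post_init__(self) -> None:
        if self.density <= 0 or self.kinematic_viscosity <= 0:
            raise ValueError("fluid properties must be positive")

    @property
    def density_cgs(self) -> float:
        """Density in g/cm^3."""
        return self.density / 1000.0
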