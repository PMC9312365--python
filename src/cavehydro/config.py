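"""Validated run configuration and machine-readable run reports.

Defaults are the study conditions: the 8.6 cm specimen, the 40x25x8 cm
tank, water at 17 °C with tabulated density 991 kg/m^3, and an added-mass
coefficient k = 0.045. The k default follows the running text of the
source study; its symbol table prints 0.45 — loading a config that leaves
k at the default records a warning in the run report so the choice is
auditable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .core import FluidProperties, Morphometry, TankGeometry
from .drag import DEFAULT_ADDED_MASS_K

__all__ = ["RunConfig", "RunReport", "load_config", "save_config"]


class MorphometryConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    bl_cm: float = 8.6
    bh_cm: float = 2.2
    bw_cm: float = 1.1
    area_cm2: float = 36.6
    volume_cm3: float = 4.4
    mass_g: float = 4.84

    def build(self) -> Morphometry:
        return Morphometry(
            bl=self.bl_cm,
            bh=self.bh_cm,
            bw=self.bw_cm,
            area=self.area_cm2,
            volume=self.volume_cm3,
            mass=self.mass_g,
        )


class TankConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    lx_cm: float = 40.0
    ly_cm: float = 25.0
    lz_cm: float = 8.0

    def build(self) -> TankGeometry:
        return TankGeometry(lx=self.lx_cm, ly=self.ly_cm, lz=self.lz_cm)


class FluidConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    density_kg_m3: float = 991.0
    kinematic_viscosity_m2_s: float = 1.085e-6

    def build(self) -> FluidProperties:
        return FluidProperties(
            density=self.density_kg_m3,
            kinematic_viscosity=self.kinematic_viscosity_m2_s,
        )


class ThresholdsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    wall_threshold_bl: float = 0.25
    bin_minutes: float = 30.0
    sensing_z: float = 5.0
    u_floor_cm_s: float = 0.2
    accel_min_cm_s2: float = 2.0
    smooth_window_s: float = 0.2
    min_burst_s: float = 0.2
    min_coast_s: float = 0.4


class RunConfig(BaseModel):
    """Top-level validated configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    morphometry: MorphometryConfig = Field(default_factory=MorphometryConfig)
    tank: TankConfig = Field(default_factory=TankConfig)
    fluid: FluidConfig = Field(default_factory=FluidConfig)
    thresholds: ThresholdsConfig = Field(default_factory=ThresholdsConfig)
    added_mass_k: float = DEFAULT_ADDED_MASS_K
    seed: int = 0
    out_dir: str = "cavehydro_out"

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def warnings(self) -> list[str]:
        notes = []
        if self.added_mass_k == DEFAULT_ADDED_MASS_K:
            notes.append(
                "added_mass_k left at the default 0.045 (study text value; "
                "the study's symbol table prints 0.45)"
            )
        if self.fluid.density_kg_m3 == 991.0:
            notes.append(
                "water density left at the tabulated 991 kg/m^3 "
                "(pure water at 17 degC is ~998.8)"
            )
        return notes


class RunReport(BaseModel):
    """Machine-readable record emitted by every pipeline run."""

    stage: str
    config_hash: str
    seed: int
    inputs: dict[str, int] = Field(default_factory=dict)
    outputs: dict[str, int] = Field(default_factory=dict)
    warnings: list[str] = Field(default_factory=list)
    elapsed_s: float = 0.0

    def write(self, path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2) + "\n")


def load_config(path=None) -> RunConfig:
    """Load and validate a YAML config; an empty/absent file yields defaults.

    Unknown keys raise a validation error naming the offending key path.
    """
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig.model_validate(data)


def save_config(path, config: RunConfig) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
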