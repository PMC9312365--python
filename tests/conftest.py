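import numpy as np
import pytest

from cavehydro import BodyContour, FluidProperties, Morphometry, TankGeometry


@pytest.fixture
def morph() -> Morphometry:
    """Study-specimen morphometry (BL 8.6 cm)."""
    return Morphometry()


@pytest.fixture
def fluid() -> FluidProperties:
    """Water at 17 degC with the tabulated density."""
    return FluidProperties()


@pytest.fixture
def tank() -> TankGeometry:
    """The 40 x 25 x 8 cm behavior tank."""
    return TankGeometry()


def make_cylinder(n: int, radius: float = 1.0) -> BodyContour:
    """Unit-circle contour discretized as a regular n-gon (CCW)."""
    theta = 2 * np.pi * (np.arange(n) + 0.5) / n
    return BodyContour(
        np.column_stack([radius * np.cos(theta), radius * np.sin(theta)]),
        label="cylinder",
    )


@pytest.fixture
def cylinder120() -> BodyContour:
    return make_cylinder(120)
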