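"""Fluid properties of cerebrospinal fluid.

CSF is modeled as an incompressible Newtonian fluid with the properties of
water at body temperature (37 C).
"""

from __future__ import annotations

from dataclasses import dataclass

DEFAULT_DENSITY = 993.0            # kg/m^3
DEFAULT_VISCOSITY = 6.97e-4        # Pa.s


@dataclass(frozen=True)
class FluidProperties:
    density: float = DEFAULT_DENSITY
    dynamic_viscosity: float = DEFAULT_VISCOSITY

    def __post_init__(self):
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise ValueError("fluid properties must be positive")

    @property
    def kinematic_viscosity(self) -> float:
        """nu = mu / rho, m^2/s."""
        return self.dynamic_viscosity / self.density


CSF = FluidProperties()
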