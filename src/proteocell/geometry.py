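"""Well geometry: the fluid column standing on a circular biomaterial disk.

The culture-well fluid is modelled as a quiescent 1D column whose cross
section equals the disk's top face.  All fluid <-> surface mass conversions
go through this object, so the areal density implied by a measured fluid
depletion is fixed by two numbers: the pipetted volume and the disk diameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class WellGeometry:
    """Fluid column over a circular disk.

    Parameters
    ----------
    fluid_volume_uL : float
        Medium volume pipetted onto the disk, in microlitres (1 uL = 1 mm^3).
    disk_diameter_mm : float
        Diameter of the disk's top face, in millimetres.

    Attributes
    ----------
    area_mm2 : float
        Disk top-face area, pi * (d/2)^2.
    height_mm : float
        Height of the fluid column, volume / area.
    """

    fluid_volume_uL: float = 200.0
    disk_diameter_mm: float = 6.0
    area_mm2: float = field(init=False)
    height_mm: float = field(init=False)

    def __post_init__(self) -> None:
        if self.fluid_volume_uL <= 0:
            raise ValueError(f"fluid_volume_uL must be > 0, got {self.fluid_volume_uL}")
        if self.disk_diameter_mm <= 0:
            raise ValueError(f"disk_diameter_mm must be > 0, got {self.disk_diameter_mm}")
        area = math.pi * (self.disk_diameter_mm / 2.0) ** 2
        object.__setattr__(self, "area_mm2", area)
        object.__setattr__(self, "height_mm", self.fluid_volume_uL / area)

    @property
    def volume_mL(self) -> float:
        """Fluid volume in millilitres (1 mL = 1000 mm^3)."""
        return self.fluid_volume_uL / 1000.0

    def fluid_to_surface(self, delta_c_ug_per_mL: float) -> float:
        """Convert a fluid-phase concentration change (ug/mL) to the areal
        surface density (ug/mm^2) holding the same mass.

        A depletion of ``delta_c`` across the whole volume corresponds to
        ``delta_c * V[mL] / A[mm^2]`` micrograms per square millimetre of
        disk face.
        """
        return delta_c_ug_per_mL * self.volume_mL / self.area_mm2

    def surface_to_fluid(self, delta_cs_ug_per_mm2: float) -> float:
        """Inverse of :meth:`fluid_to_surface` (ug/mm^2 -> ug/mL)."""
        return delta_cs_ug_per_mm2 * self.area_mm2 / self.volume_mL


DEFAULT_GEOMETRY = WellGeometry()
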