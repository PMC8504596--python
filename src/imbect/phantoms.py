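"""Synthetic phantoms, target volumes and apertures for desk-scale planning.

Everything downstream of the beam model operates on a voxelised relative
electron density grid (water = 1.0) expressed in beam coordinates (source at
z = 0, beam along +z).  The generators here provide the two study geometries:

* a uniform water tank, the clinical-QA stand-in for the patient, and
* a "wavy slab": a flat-entrance water phantom whose target volume has a
  sinusoidal distal surface.  After conformal-bolus design the rippled bolus
  this induces focuses and defocuses the electron fluence and produces the
  hot spots that motivate intensity modulation.

Voxel convention: continuous cm coordinates; the center of voxel (0,0,0) is
at ``origin + spacing/2``; voxel extents are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Aperture

__all__ = [
    "DensityGrid",
    "water_tank",
    "wavy_slab_phantom",
    "rectangular_aperture",
]


@dataclass(frozen=True)
class DensityGrid:
    """Voxelised relative electron density in beam coordinates.

    ``values[ix, iy, iz]`` with the z axis along the beam, increasing away
    from the source.  ``origin`` is the lower corner of voxel (0, 0, 0).
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if np.any(self.values < 0):
            raise ValueError("densities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    @property
    def x(self) -> np.ndarray:
        return self.axis_centers(0)

    @property
    def y(self) -> np.ndarray:
        return self.axis_centers(1)

    @property
    def z(self) -> np.ndarray:
        return self.axis_centers(2)

    @property
    def surface_z(self) -> float:
        """z of the upstream (entrance) face of the grid."""
        return self.origin[2]


def water_tank(
    extent: tuple[float, float, float] = (12.0, 12.0, 10.0),
    spacing: tuple[float, float, float] = (0.2, 0.2, 0.2),
    ssd: float = 100.0,
) -> DensityGrid:
    """Uniform water phantom with its top surface at the stated SSD.

    Laterally centered on the beam axis; ``extent`` is (x, y, depth) in cm.
    """
    if any(e <= 0 for e in extent) or any(s <= 0 for s in spacing):
        raise ValueError("extents and spacings must be positive")
    shape = tuple(int(round(e / s)) for e, s in zip(extent, spacing))
    origin = (-extent[0] / 2.0, -extent[1] / 2.0, ssd)
    return DensityGrid(origin=origin, spacing=spacing, values=np.ones(shape))


def wavy_slab_phantom(
    ptv_distal_amplitude: float = 0.5,
    period: float = 8.0,
    *,
    extent: tuple[float, float, float] = (14.0, 14.0, 8.0),
    spacing: tuple[float, float, float] = (0.2, 0.2, 0.2),
    ssd: float = 100.0,
    ptv_proximal_depth: float = 0.4,
    ptv_distal_depth: float = 3.0,
    ptv_half_width: tuple[float, float] = (3.0, 3.0),
) -> tuple[DensityGrid, np.ndarray]:
    """Flat-entrance water slab with a sinusoidal distal PTV surface.

    The PTV occupies ``|x| <= hw_x``, ``|y| <= hw_y`` between the proximal
    depth and a distal depth ``d(x) = ptv_distal_depth +
    amplitude * sin(2*pi*x/period)`` (peak-to-peak range ``2*amplitude``).
    Amplitude 0 reduces to a flat slab PTV.

    Returns the density grid and the congruent boolean PTV mask.
    """
    if ptv_distal_amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    grid = water_tank(extent=extent, spacing=spacing, ssd=ssd)
    x, y, z = grid.x, grid.y, grid.z
    depth = z - ssd
    distal = ptv_distal_depth + ptv_distal_amplitude * np.sin(2.0 * np.pi * x / period)
    lateral = (np.abs(x)[:, None] <= ptv_half_width[0]) & (
        np.abs(y)[None, :] <= ptv_half_width[1]
    )
    in_z = (depth[None, None, :] >= ptv_proximal_depth) & (
        depth[None, None, :] <= distal[:, None, None]
    )
    ptv = lateral[:, :, None] & in_z
    if not ptv.any():
        raise ValueError("degenerate parameters produced an empty PTV")
    return grid, ptv


def rectangular_aperture(width: float, height: float) -> Aperture:
    """Centered rectangular aperture specified in the isocenter plane."""
    if width <= 0 or height <= 0:
        raise ValueError("aperture sides must be positive")
    w, h = width / 2.0, height / 2.0
    return Aperture(vertices=np.array([[-w, -h], [w, -h], [w, h], [-w, h]]))
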