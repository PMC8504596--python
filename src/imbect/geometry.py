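"""Beam-eye coordinate system and divergent-beam projection helpers.

All geometry lives in the beam coordinate system: the virtual electron point
source sits at ``z = 0``, the beam axis is +z, isocenter is at ``z = 100`` cm
and the collimator/modulator plane at ``z = 93.5`` cm.  Any off-axis point
projects between planes by similar triangles about the source:
``x(z) = x(z0) * z / z0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

ISOCENTER_Z_CM = 100.0


def project(coords, z_from: float, z_to: float):
    """Scale lateral coordinates from plane ``z_from`` to plane ``z_to``."""
    return np.asarray(coords, dtype=float) * (z_to / z_from)


@dataclass(frozen=True)
class Aperture:
    """Beam-defining aperture polygon, specified in the isocenter plane.

    ``vertices`` is an (N, 2) array of (x, y) cm at 100 cm from the source;
    ``collimator_z`` is the plane of the physical insert (default 93.5 cm).
    """

    vertices: np.ndarray
    collimator_z: float = 93.5

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        object.__setattr__(self, "vertices", v)
        poly = shapely.Polygon(v)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError("aperture must be a simple polygon with positive area")

    @property
    def polygon(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices)

    @property
    def area(self) -> float:
        return self.polygon.area

    def polygon_at(self, z: float) -> shapely.Polygon:
        """Aperture outline projected to plane ``z`` by similar triangles."""
        return shapely.Polygon(project(self.vertices, ISOCENTER_Z_CM, z))

    def contains_points(self, x, y, z: float = ISOCENTER_Z_CM) -> np.ndarray:
        """Boolean membership of points (x, y) given in plane ``z``."""
        poly = self.polygon_at(z)
        return shapely.contains_xy(poly, np.asarray(x, float), np.asarray(y, float))

    def bounding_box(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the effective (circumscribing) field."""
        return self.polygon.bounds
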