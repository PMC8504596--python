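"""Objective intensity map: intensity reduction factors from a BECT dose.

After conformal-bolus design the dose inside the PTV may contain hot spots
(dose above 100% when prescribing to the 90% surface).  The intensity
modulation operator flattens them: for each fan line whose ray stays a
stated margin (default 0.5 cm) inside the PTV edge, the maximum dose along
the ray inside the PTV, ``Dmax``, maps to an intensity reduction factor

* ``IRF = 1``            for ``Dmax < 100%``,
* ``IRF = 100 / Dmax``   for ``100% <= Dmax <= 125%``,
* ``IRF = 0.8``          for ``Dmax > 125%``,

so the IRF is continuous, non-increasing and clamped to [0.8, 1.0] — the
upper threshold is the reciprocal of the minimum IRF (``0.8**-1 = 125%``),
the unique value at which the ratio meets the clamp continuously.  Fan
lines outside the margin inherit the nearest eligible line's IRF (the same
nearest-neighbour rule used for bolus height extension).  The limits are
user-configurable; 0.8/1.0 are the study defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt

from .bolus import eroded_ptv_projection
from .engine import Dose3D

__all__ = ["IntensityMap", "ray_max_dose", "irf_from_dmax", "build_intensity_map"]


@dataclass(frozen=True)
class IntensityMap:
    """Per-fan-line intensity reduction factors on the planning lattice."""

    x: np.ndarray
    y: np.ndarray
    irf: np.ndarray = field(repr=False)
    eligible: np.ndarray = field(repr=False, default=None)
    margin: float = 0.5

    def __post_init__(self):
        if np.any(self.irf < 0) or np.any(self.irf > 1.0 + 1e-12):
            raise ValueError("IRF values must lie in [0, 1]")


def ray_max_dose(dose: Dose3D, ptv: np.ndarray, margin: float = 0.5) -> np.ndarray:
    """Maximum percent dose along each eligible ray inside the PTV.

    Dose is sampled at half the grid spacing along z (linear interpolation
    between voxel centers); columns whose ray misses the eroded PTV are
    NaN (ineligible).  Raises if no line is eligible (margin larger than
    the PTV's lateral half-width).
    """
    grid = dose.grid
    eligible = eroded_ptv_projection(ptv, grid, margin)
    if not eligible.any():
        raise ValueError("no eligible fan lines: margin exceeds the PTV extent")
    v = dose.values
    masked = np.where(ptv, v, -np.inf)
    dmax = masked.max(axis=2)
    # midpoint samples (step = dz/2): linear dose, both-neighbour PTV membership
    mid = 0.5 * (v[:, :, :-1] + v[:, :, 1:])
    mid_in = ptv[:, :, :-1] & ptv[:, :, 1:]
    mid_masked = np.where(mid_in, mid, -np.inf)
    if mid_masked.size:
        dmax = np.maximum(dmax, mid_masked.max(axis=2))
    return np.where(eligible & np.isfinite(dmax), dmax, np.nan)


def irf_from_dmax(dmax, irf_min: float = 0.8):
    """Intensity reduction factor for a ray's maximum percent dose."""
    d = np.asarray(dmax, dtype=float)
    if np.any(~np.isfinite(d)) or np.any(d <= 0):
        raise ValueError("dmax must be positive and finite")
    thresh = 100.0 / irf_min
    out = np.where(d < 100.0, 1.0, np.where(d > thresh, irf_min, 100.0 / d))
    return float(out) if np.isscalar(dmax) else out


def build_intensity_map(
    dose: Dose3D,
    ptv: np.ndarray,
    margin: float = 0.5,
    irf_min: float = 0.8,
    irf_max: float = 1.0,
) -> IntensityMap:
    """Objective IRF map from a dose distribution.

    Eligible lines get ``irf_from_dmax``; ineligible lines the nearest
    eligible value; everything is clamped to ``[irf_min, irf_max]``.
    """
    grid = dose.grid
    dmax = ray_max_dose(dose, ptv, margin)
    eligible = np.isfinite(dmax)
    irf = np.ones(dmax.shape)
    irf[eligible] = irf_from_dmax(dmax[eligible], irf_min=irf_min)
    _, (ix, iy) = distance_transform_edt(~eligible, return_indices=True)
    irf = irf[ix, iy]
    irf = np.clip(irf, irf_min, irf_max)
    return IntensityMap(x=grid.x, y=grid.y, irf=irf, eligible=eligible, margin=margin)
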