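"""Conformal bolus design operators and operator sequences.

A variable-thickness wax bolus abutting the patient surface modulates the
electron range laterally so that the 90% dose surface conforms to
(circumscribes) the distal PTV surface.  The design is expressed as a small
algebra of operators applied in sequence:

* **Create** — per fan line inside the (laterally eroded) PTV, set the
  thickness so the physical depth of the prescribed percent dose lands on
  the distal PTV surface.
* **Isodose Shift** — after a dose calculation, nudge each line's thickness
  by the residual between the actual depth of the 90% surface and the
  distal PTV depth.
* **Smooth** — convolve the height map with a truncated radial Gaussian.
* **Specified Shift** — add/subtract a uniform thickness (floored at 0).
* **Truncate** — remove bolus outside the treatment field to cut mass,
  leaving the in-field dose unchanged.
* **Height Extension** — fill fan lines outside the eligible region with
  the value of the nearest eligible line.
* **Intensity Modulation** — derive an intensity-reduction-factor map from
  the current dose and fold it into the pencil weights (see
  :mod:`imbect.modulation`); the sequence may then reoptimise the bolus.

All maps live on the planning fan-line lattice, which for these operators
coincides with the dose grid's lateral lattice (small-angle convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from scipy.ndimage import binary_erosion, convolve, distance_transform_edt

from .beam import BeamModel
from .engine import Dose3D, compute_dose, radiological_depth_columns
from .fluence import FanLineGrid
from .geometry import Aperture
from .phantoms import DensityGrid

__all__ = [
    "BolusSurface",
    "op_create",
    "op_isodose_shift",
    "op_smooth",
    "op_specified_shift",
    "op_truncate",
    "op_height_extension",
    "run_sequence",
    "PlanResult",
    "conformality",
]


@dataclass(frozen=True)
class BolusSurface:
    """Per-fan-line bolus thickness map.

    ``thickness[ix, iy]`` in cm of bolus material; ``density`` is the bolus
    relative electron density (machinable wax, default 0.92), used to
    convert physical thickness to water-equivalent thickness.
    """

    x: np.ndarray
    y: np.ndarray
    thickness: np.ndarray = field(repr=False)
    density: float = 0.92
    footprint: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        t = np.asarray(self.thickness, dtype=float)
        if np.any(~np.isfinite(t)) or np.any(t < 0):
            raise ValueError("bolus thickness must be finite and non-negative")
        object.__setattr__(self, "thickness", t)
        if self.footprint is None:
            object.__setattr__(self, "footprint", np.ones(t.shape, dtype=bool))

    def water_equivalent_map(self, x, y) -> np.ndarray:
        """WET sampled on the given lateral lattice (bilinear)."""
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator(
            (self.x, self.y), self.thickness * self.density,
            bounds_error=False, fill_value=0.0,
        )
        gx, gy = np.meshgrid(x, y, indexing="ij")
        return interp(np.stack([gx, gy], axis=-1))

    def water_equivalent_at(self, x: float, y: float) -> float:
        return float(self.water_equivalent_map(np.atleast_1d(x), np.atleast_1d(y))[0, 0])

    @property
    def mass_proxy(self) -> float:
        """Sum of thickness times lattice-cell area (relative mass)."""
        dx = self.x[1] - self.x[0]
        dy = self.y[1] - self.y[0]
        return float(self.thickness.sum() * dx * dy)


# ---------------------------------------------------------------------------
# eligibility and column geometry helpers


def eroded_ptv_projection(ptv: np.ndarray, grid: DensityGrid, margin: float) -> np.ndarray:
    """Fan lines whose rays pass inside the PTV eroded laterally by ``margin``."""
    proj = ptv.any(axis=2)
    if margin <= 0:
        return proj
    dx = grid.spacing[0]
    r = int(np.floor(margin / dx))
    if r == 0:
        return proj
    ax = np.arange(-r, r + 1)
    disk = ax[:, None] ** 2 + ax[None, :] ** 2 <= (margin / dx) ** 2
    return binary_erosion(proj, structure=disk)


def distal_ptv_depth(ptv: np.ndarray, grid: DensityGrid) -> np.ndarray:
    """z coordinate of the distal PTV face per column (NaN where no PTV)."""
    nz = ptv.shape[2]
    has = ptv.any(axis=2)
    last = nz - 1 - np.argmax(ptv[:, :, ::-1], axis=2)
    z_distal = grid.z[last] + grid.spacing[2] / 2.0
    return np.where(has, z_distal, np.nan)


def distal_ptv_wed(ptv: np.ndarray, grid: DensityGrid) -> np.ndarray:
    """Water-equivalent depth of the distal PTV face per column (no bolus)."""
    deff = radiological_depth_columns(grid)
    nz = ptv.shape[2]
    has = ptv.any(axis=2)
    last = nz - 1 - np.argmax(ptv[:, :, ::-1], axis=2)
    ii, jj = np.meshgrid(np.arange(ptv.shape[0]), np.arange(ptv.shape[1]), indexing="ij")
    wed = deff[ii, jj, last] + grid.values[ii, jj, last] * grid.spacing[2] / 2.0
    return np.where(has, wed, np.nan)


def depth_of_90(dose: Dose3D, level: float = 90.0) -> tuple[np.ndarray, np.ndarray]:
    """Deepest downstream crossing of ``level`` per column.

    Returns (z90, found): ``z90`` is the interpolated z coordinate of the
    deepest crossing; ``found`` flags columns with such a crossing.
    """
    v = dose.values
    z = dose.grid.z
    dz = dose.grid.spacing[2]
    above = v >= level
    found = above.any(axis=2)
    nz = v.shape[2]
    last = nz - 1 - np.argmax(above[:, :, ::-1], axis=2)
    ii, jj = np.meshgrid(np.arange(v.shape[0]), np.arange(v.shape[1]), indexing="ij")
    z90 = z[last].astype(float)
    interior = found & (last < nz - 1)
    d0 = v[ii, jj, np.minimum(last, nz - 1)]
    d1 = v[ii, jj, np.minimum(last + 1, nz - 1)]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(d0 > d1, (d0 - level) / (d0 - d1), 0.0)
    z90 = np.where(interior, z90 + np.clip(frac, 0.0, 1.0) * dz, z90)
    return np.where(found, z90, np.nan), found


# ---------------------------------------------------------------------------
# operators


def op_create(
    ptv: np.ndarray,
    grid: DensityGrid,
    beam: BeamModel,
    percent: float = 90.0,
    inner_margin: float = 0.7,
    density: float = 0.92,
) -> BolusSurface:
    """Create a bolus conforming the ``percent`` dose depth to the distal PTV.

    Per fan line inside the PTV eroded laterally by ``inner_margin``, the
    thickness is ``(R_percent − WED_distal)/density`` floored at zero; lines
    outside get the nearest-eligible value (height extension rule).
    """
    if not ptv.any():
        raise ValueError("PTV is empty")
    eligible = eroded_ptv_projection(ptv, grid, inner_margin)
    if not eligible.any():
        raise ValueError("margin erosion removed the entire PTV projection")
    r_pct = beam.depth_of_percent(percent)
    wed = distal_ptv_wed(ptv, grid)
    t = np.zeros(eligible.shape)
    t[eligible] = np.maximum(r_pct - wed[eligible], 0.0) / density
    bolus = BolusSurface(x=grid.x, y=grid.y, thickness=t, density=density)
    return op_height_extension(bolus, eligible)


def op_isodose_shift(
    bolus: BolusSurface,
    dose: Dose3D,
    ptv: np.ndarray,
    inner_margin: float = 0.5,
) -> tuple[BolusSurface, int]:
    """Shift thickness by the residual depth of the 90% surface.

    For each eligible fan line the thickness changes by
    ``(z90 − z_distalPTV)/density`` (water-equivalent residual converted to
    bolus material), floored at zero.  Lines without a 90% crossing are left
    unchanged; their count is returned alongside the new bolus.
    """
    grid = dose.grid
    eligible = eroded_ptv_projection(ptv, grid, inner_margin)
    z90, found = depth_of_90(dose)
    z_distal = distal_ptv_depth(ptv, grid)
    act = eligible & found & np.isfinite(z_distal)
    t = bolus.thickness.copy()
    t[act] = np.maximum(t[act] + (z90[act] - z_distal[act]) / bolus.density, 0.0)
    skipped = int(np.count_nonzero(eligible & ~found))
    return replace(bolus, thickness=t), skipped


def op_smooth(
    bolus: BolusSurface, exp_mult: float = 2.0, radius_mult: float = 1.0
) -> BolusSurface:
    """Convolve the height map with a truncated radial Gaussian.

    Kernel ``exp(−exp_mult (rho/R)^2)`` truncated at ``rho = R`` with
    ``R = radius_mult * 1.5`` cm, normalised, and renormalised at footprint
    edges so a uniform bolus is left unchanged.
    """
    r_cm = radius_mult * 1.5
    dx = bolus.x[1] - bolus.x[0]
    r_px = int(np.floor(r_cm / dx))
    ax = np.arange(-r_px, r_px + 1) * dx
    rho2 = ax[:, None] ** 2 + ax[None, :] ** 2
    kernel = np.exp(-exp_mult * rho2 / r_cm**2)
    kernel[rho2 > r_cm**2] = 0.0
    kernel /= kernel.sum()
    m = bolus.footprint.astype(float)
    num = convolve(bolus.thickness * m, kernel, mode="constant")
    den = convolve(m, kernel, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = np.where(den > 0, num / den, 0.0)
    t = np.where(bolus.footprint, sm, bolus.thickness)
    return replace(bolus, thickness=np.maximum(t, 0.0))


def op_specified_shift(bolus: BolusSurface, delta: float) -> BolusSurface:
    """Add ``delta`` cm to the whole proximal surface, floored at zero."""
    t = np.where(bolus.footprint, np.maximum(bolus.thickness + delta, 0.0), bolus.thickness)
    return replace(bolus, thickness=t)


def op_truncate(
    bolus: BolusSurface, aperture: Aperture, margin: float = 1.0
) -> BolusSurface:
    """Zero the bolus outside the projected aperture plus ``margin``.

    The margin retains enough out-of-field bolus that in-field dose is
    unchanged (within the engine's scatter reach); mass strictly decreases
    whenever the footprint extended beyond the field.
    """
    gx, gy = np.meshgrid(bolus.x, bolus.y, indexing="ij")
    poly = aperture.polygon.buffer(margin)
    inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(gx.shape)
    t = np.where(inside, bolus.thickness, 0.0)
    return replace(bolus, thickness=t, footprint=inside)


def op_height_extension(bolus: BolusSurface, eligible: np.ndarray) -> BolusSurface:
    """Fill ineligible fan lines with the nearest eligible line's value."""
    if not eligible.any():
        raise ValueError("no eligible fan lines to extend from")
    if eligible.all():
        return bolus
    _, (ix, iy) = distance_transform_edt(~eligible, return_indices=True)
    return replace(bolus, thickness=bolus.thickness[ix, iy])


# ---------------------------------------------------------------------------
# sequences


@dataclass
class PlanResult:
    bolus: BolusSurface | None
    intensity: object | None
    dose: Dose3D | None
    fan: FanLineGrid
    log: list[dict]


def run_sequence(
    steps,
    grid: DensityGrid,
    ptv: np.ndarray,
    beam: BeamModel,
    aperture: Aperture,
    *,
    bolus_density: float = 0.92,
    irf_min: float = 0.8,
    irf_max: float = 1.0,
) -> PlanResult:
    """Execute an operator sequence (the planning workflow driver).

    ``steps`` is an ordered list of ``(name, params)`` pairs (or dicts with
    an ``op`` key) using the operator vocabulary: ``create``, ``smooth``,
    ``isodose_shift``, ``specified_shift``, ``truncate``,
    ``intensity_modulation``.  Dose is recomputed whenever an operator needs
    it, and once more at the end.  Returns the final bolus, the intensity
    map if modulation was applied, the final dose, the (possibly modulated)
    fan weights, and a log with one entry per operator.
    """
    from .modulation import build_intensity_map

    x, y = grid.x, grid.y
    inside = aperture.contains_points(
        np.repeat(x, y.size), np.tile(y, x.size)
    ).reshape(x.size, y.size)
    fan = FanLineGrid(x=x, y=y, weights=inside.astype(float), spacing=float(grid.spacing[0]))

    bolus: BolusSurface | None = None
    intensity = None
    dose: Dose3D | None = None
    log: list[dict] = []

    def fresh_dose() -> Dose3D:
        return compute_dose(grid, fan, beam, ptv=ptv, bolus=bolus)

    for step in steps:
        if isinstance(step, dict):
            name = step.get("op")
            params = {k: v for k, v in step.items() if k != "op"}
        else:
            name, params = step[0], dict(step[1]) if len(step) > 1 else {}
        entry: dict = {"op": name, "params": dict(params)}
        if name == "create":
            bolus = op_create(ptv, grid, beam, density=bolus_density, **params)
        elif name == "smooth":
            _require(bolus, name)
            bolus = op_smooth(bolus, **params)
        elif name == "isodose_shift":
            _require(bolus, name)
            dose = fresh_dose()
            bolus, skipped = op_isodose_shift(bolus, dose, ptv, **params)
            entry["lines_without_crossing"] = skipped
        elif name == "specified_shift":
            _require(bolus, name)
            bolus = op_specified_shift(bolus, **params)
        elif name == "truncate":
            _require(bolus, name)
            bolus = op_truncate(bolus, aperture, **params)
        elif name == "intensity_modulation":
            dose = fresh_dose()
            intensity = build_intensity_map(
                dose, ptv, irf_min=irf_min, irf_max=irf_max, **params
            )
            fan = fan.with_weights(fan.weights * intensity.irf)
            entry["irf_range"] = [float(intensity.irf.min()), float(intensity.irf.max())]
        else:
            raise ValueError(f"unknown operator: {name!r}")
        log.append(entry)

    if steps:
        dose = fresh_dose()
    return PlanResult(bolus=bolus, intensity=intensity, dose=dose, fan=fan, log=log)


def _require(bolus, name):
    if bolus is None:
        raise ValueError(f"operator {name!r} requires an existing bolus (run create first)")


def conformality(
    dose: Dose3D, ptv: np.ndarray, inner_margin: float = 0.5, tol: float = 0.2
) -> float:
    """Fraction of eligible fan lines with |z90 − z_distalPTV| <= ``tol`` cm."""
    grid = dose.grid
    eligible = eroded_ptv_projection(ptv, grid, inner_margin)
    z90, found = depth_of_90(dose)
    z_d = distal_ptv_depth(ptv, grid)
    ok = eligible & found & (np.abs(z90 - z_d) <= tol)
    return float(np.count_nonzero(ok) / np.count_nonzero(eligible))
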