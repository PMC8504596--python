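"""Pencil-beam electron dose engine.

Dose at a point is the sum of an electron component and a background x-ray
component.  The electron component is computed in a single pass: the
aperture-collimated (and optionally island-block-modulated) surface fluence
is transported slice by slice into the density grid, each surface column
contributing a Gaussian pencil whose width follows a Fermi-Eyges
accumulation of multiple Coulomb scattering over that column's radiological
depth.  Because each column scatters with its *own* accumulated sigma,
lateral gradients of bolus thickness redistribute fluence — thick regions
spray electrons sideways into thin regions — which is precisely the
mechanism that creates the hot and cold spots conformal bolus can induce.

The x-ray background is a simple ramped tail: zero at the surface rising
linearly to the beam's tail level at the practical range, constant beyond,
and unaffected by island blocks (bremsstrahlung is generated upstream and
is not stopped by the pins).

Doses are percent of "given dose": the open-field central-axis maximum in
water at the nominal SSD for the effective field — the rectangular field of
minimum area circumscribing the aperture.  Because the tabulated PDD is a
measured central-axis curve it already contains the lateral-equilibrium
loss of the reference field; each slice is therefore renormalised by the
analytic equilibrium factor of the effective field at the slice's water
depth (a product of error functions), so that in open water the
central-axis dose reproduces the PDD exactly.  Output-factor variation
beyond this equilibrium factor is not modelled.

Approximations (documented, desk-scale): radiological depth and column
bookkeeping inside the grid use vertical columns (small-angle approximation
of the fan divergence); :func:`effective_depth` itself integrates along the
true diverging ray.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .beam import BeamModel, apply_modulator_corrections
from .fluence import FanLineGrid, SurfaceFluence, transport_fluence
from .geometry import ISOCENTER_Z_CM, Aperture
from .phantoms import DensityGrid
from .planar import PlanarDose

__all__ = ["Dose3D", "effective_depth", "compute_dose", "planar_dose"]

_N_SIGMA_BINS = 8


@dataclass(frozen=True)
class Dose3D:
    """Dose congruent with a :class:`DensityGrid`, percent of given dose."""

    grid: DensityGrid
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.values.shape != self.grid.shape:
            raise ValueError("dose must be congruent with its density grid")
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("dose values must be finite and non-negative")


def _sigma_mcs_table(beam: BeamModel) -> tuple[np.ndarray, np.ndarray]:
    d = np.linspace(0.0, beam.rp + 3.0, 120)
    return d, beam.sigma_mcs(d)


def effective_depth(
    grid: DensityGrid,
    ray,
    point_z: float,
    bolus=None,
) -> float:
    """Radiological (water-equivalent) pathlength along a diverging ray.

    ``ray`` is the fan-line position (x, y) in the isocenter plane.  The
    relative electron density is integrated along the ray from the grid's
    entrance face to ``point_z``; a bolus, if present, adds its
    water-equivalent thickness at that fan line.  A ray that misses the
    grid contributes 0.
    """
    x_iso, y_iso = ray
    z0, z1 = grid.surface_z, float(point_z)
    if z1 <= z0:
        return _bolus_wet(bolus, x_iso, y_iso)
    step = grid.spacing[2] / 4.0
    z = np.arange(z0 + step / 2.0, z1, step)
    xs = x_iso * z / ISOCENTER_Z_CM
    ys = y_iso * z / ISOCENTER_Z_CM
    nx, ny, nz = grid.shape
    ix = (xs - grid.origin[0]) / grid.spacing[0] - 0.5
    iy = (ys - grid.origin[1]) / grid.spacing[1] - 0.5
    iz = (z - grid.origin[2]) / grid.spacing[2] - 0.5
    inside = (
        (ix > -0.5) & (ix < nx - 0.5) & (iy > -0.5) & (iy < ny - 0.5)
        & (iz > -0.5) & (iz < nz - 0.5)
    )
    coords = [np.clip(ix, 0, nx - 1), np.clip(iy, 0, ny - 1), np.clip(iz, 0, nz - 1)]
    rho = map_coordinates(grid.values, coords, order=1, mode="nearest") * inside
    return float(np.sum(rho) * step) + _bolus_wet(bolus, x_iso, y_iso)


def _bolus_wet(bolus, x_iso: float, y_iso: float) -> float:
    if bolus is None:
        return 0.0
    return bolus.water_equivalent_at(x_iso, y_iso)


def radiological_depth_columns(grid: DensityGrid, bolus=None) -> np.ndarray:
    """Water-equivalent depth of every voxel center along vertical columns.

    Returns an array congruent with the grid; a bolus adds its
    water-equivalent thickness map (sampled at the column positions) on top.
    """
    dz = grid.spacing[2]
    rho = grid.values
    # depth to voxel centers: half the first voxel plus full voxels above
    cum = np.cumsum(rho, axis=2) * dz
    deff = cum - rho * dz / 2.0
    if bolus is not None:
        wet = bolus.water_equivalent_map(grid.x, grid.y)
        deff = deff + wet[:, :, None]
    return deff


def _equilibrium_factor(width: float, height: float, sigma: float) -> float:
    """Central lateral-scatter equilibrium factor of a w x h field.

    Fraction of a centered Gaussian pencil integral retained inside the
    field, evaluated at the field center: ``erf(w/(2 sqrt2 sigma)) *
    erf(h/(2 sqrt2 sigma))``; 1 for sigma -> 0.
    """
    from scipy.special import erf

    if sigma <= 1e-9:
        return 1.0
    s = 2.0 * np.sqrt(2.0) * sigma
    return float(erf(width / s) * erf(height / s))


def _effective_field(fan: FanLineGrid, aperture: Aperture | None) -> tuple[float, float]:
    """Width/height of the circumscribing rectangle of the open field (isocenter)."""
    if aperture is not None:
        xmin, ymin, xmax, ymax = aperture.bounding_box()
        return xmax - xmin, ymax - ymin
    open_mask = fan.weights > 0
    if not open_mask.any():
        return 0.0, 0.0
    ix = np.nonzero(open_mask.any(axis=1))[0]
    iy = np.nonzero(open_mask.any(axis=0))[0]
    return (
        float(fan.x[ix[-1]] - fan.x[ix[0]] + fan.spacing),
        float(fan.y[iy[-1]] - fan.y[iy[0]] + fan.spacing),
    )


def _varying_sigma_filter(source: np.ndarray, sigma_px: np.ndarray) -> np.ndarray:
    """Convolve a 2D source with per-source-pixel Gaussian widths.

    Sigmas are quantised into a small number of bins; each bin's sub-source
    is blurred with the bin-center width.  Fluence is conserved per source
    pixel (each normalised Gaussian integrates to one).
    """
    smin, smax = float(sigma_px.min()), float(sigma_px.max())
    if smax - smin < 1e-3:
        s = 0.5 * (smin + smax)
        return gaussian_filter(source, s, mode="nearest") if s > 1e-6 else source.copy()
    # split each source pixel linearly between its two bracketing sigma
    # levels; each level's accumulated sub-source is blurred once.  Exact for
    # uniform sigma, second-order accurate in the level spacing otherwise.
    levels = np.linspace(smin, smax, _N_SIGMA_BINS + 1)
    idx = np.clip(np.searchsorted(levels, sigma_px, side="right") - 1, 0, _N_SIGMA_BINS - 1)
    frac = (sigma_px - levels[idx]) / (levels[idx + 1] - levels[idx])
    out = np.zeros_like(source)
    for lv in range(_N_SIGMA_BINS + 1):
        sub = np.zeros_like(source)
        lower = idx == lv
        upper = idx == lv - 1
        if lower.any():
            sub[lower] = source[lower] * (1.0 - frac[lower])
        if upper.any():
            sub[upper] += source[upper] * frac[upper]
        if not sub.any():
            continue
        s = levels[lv]
        out += gaussian_filter(sub, s, mode="nearest") if s > 1e-6 else sub
    return out


def compute_dose(
    grid: DensityGrid,
    fan: FanLineGrid,
    beam: BeamModel,
    *,
    ptv: np.ndarray | None = None,
    bolus=None,
    blocks=None,
    aperture: Aperture | None = None,
) -> Dose3D:
    """3D dose from a divergent electron beam into a density grid.

    When ``blocks`` is given the beam passes through the modulator: the
    depth-dose and scattering model use the foam-corrected beam (R90 shifted
    0.1 cm shallower) and the block deficits are transported with the 1.5x
    angular spread, while the open-field spread keeps the uncorrected value.
    ``ptv`` is accepted for interface symmetry with the planning operators
    and does not influence the dose itself.
    """
    if aperture is None and not fan.weights.any():
        warnings.warn("empty aperture/weights: returning zero dose")
        return Dose3D(grid=grid, values=np.zeros(grid.shape))

    sf = transport_fluence(fan, aperture, blocks, beam, surface_z=grid.surface_z)
    beam_eff = apply_modulator_corrections(beam) if blocks is not None else beam
    deff = radiological_depth_columns(grid, bolus)
    d_tab, s_tab = _sigma_mcs_table(beam_eff)

    x, y, z = grid.x, grid.y, grid.z
    px = grid.spacing[0]
    dose = np.empty(grid.shape)
    fx = np.arange(sf.x.size)
    fy = np.arange(sf.y.size)
    fw, fh = _effective_field(fan, aperture)
    for iz, zc in enumerate(z):
        depth_w = zc - grid.surface_z
        sigma_eq = float(np.interp(depth_w, d_tab, s_tab))
        eq = _equilibrium_factor(fw * zc / ISOCENTER_Z_CM, fh * zc / ISOCENTER_Z_CM, sigma_eq)
        # fan line through grid point (x, z) pierces the surface at x*z0/z
        mscale = sf.surface_z / zc
        gx = np.interp(x * mscale, sf.x, fx)
        gy = np.interp(y * mscale, sf.y, fy)
        mx, my = np.meshgrid(gx, gy, indexing="ij")
        sf_mod = map_coordinates(sf.values, [mx, my], order=1, mode="nearest")
        sf_open = map_coordinates(sf.open_values, [mx, my], order=1, mode="nearest")

        d_slice = deff[:, :, iz]
        pdde = np.interp(d_slice, beam_eff.depths, beam_eff.percents, right=beam_eff.xray_tail)
        dx_bg = beam_eff.xray_tail * np.minimum(d_slice / beam_eff.rp, 1.0)
        source = sf_mod * np.maximum(pdde - dx_bg, 0.0)
        sigma_px = np.interp(d_slice, d_tab, s_tab) / px
        de = _varying_sigma_filter(source, sigma_px) / eq
        dose[:, :, iz] = de + sf_open * dx_bg
    return Dose3D(grid=grid, values=np.clip(dose, 0.0, None))


def planar_dose(
    beam: BeamModel,
    aperture: Aperture,
    blocks,
    depth: float,
    ssd: float = 100.0,
    pixel: float = 0.1,
    fan: FanLineGrid | None = None,
) -> PlanarDose:
    """2D percent-of-given-dose grid at ``depth`` in a water phantom.

    This is the clinical-QA geometry: patient and bolus replaced by water
    with its surface at ``ssd``; 100% equals the given dose of the beam
    without the modulator.  The default pixel is 0.1 cm in the measurement
    plane.
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    from .fluence import fan_grid_for_aperture

    if fan is None:
        fan = fan_grid_for_aperture(aperture)
    surf_pixel = pixel * ssd / (ssd + depth)
    sf = transport_fluence(fan, aperture, blocks, beam, surface_z=ssd, pixel=surf_pixel)
    beam_eff = apply_modulator_corrections(beam) if blocks is not None else beam
    pdde = beam_eff.electron_percent(depth)
    dx_bg = beam_eff.xray_background(depth)
    sig_cm = beam_eff.sigma_mcs(depth)
    sig = sig_cm / surf_pixel
    xmin, ymin, xmax, ymax = aperture.bounding_box()
    zs = ssd + depth
    eq = _equilibrium_factor(
        (xmax - xmin) * zs / ISOCENTER_Z_CM, (ymax - ymin) * zs / ISOCENTER_Z_CM, sig_cm
    )
    de = gaussian_filter(sf.values, sig, mode="nearest") if sig > 1e-6 else sf.values
    de = de * (pdde / eq)
    values = de + sf.open_values * dx_bg
    mag = (ssd + depth) / ssd
    return PlanarDose(
        x=sf.x * mag, y=sf.y * mag, values=np.clip(values, 0.0, None), depth=depth, ssd=ssd
    )
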