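"""Electron beam model: central-axis depth dose, ranges and angular spread.

The model represents a matched clinical electron beam by an analytic
percent-depth-dose (PDD) family plus the small set of scalar parameters the
planning chain needs: the therapeutic range ``R90``, the depth of maximum
dose ``R100``, the practical range ``Rp``, the initial angular spread of the
beam at the collimator, and the level of the bremsstrahlung (x-ray) tail.

The PDD is piecewise: a parabolic buildup from the surface dose to 100% at
``R100``, a monotone cosine-power falloff pinned exactly through
``(R90, 90%)`` down to the x-ray tail at ``Rp``, and a constant tail beyond.
Percent depth dose is the central-axis dose in water at the nominal SSD, so
divergence along the central axis is already folded into the curve.

When a passive intensity modulator (foam insert carrying tungsten island
blocks) sits in the beam, the foam degrades the beam slightly.  This is
modelled by two rigid corrections: the whole depth-dose curve shifts 0.1 cm
shallower (R90 decreases by 0.1 cm) and the initial angular spread increases
by 50%.  See :func:`apply_modulator_corrections`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

__all__ = ["BeamModel", "make_beam", "apply_modulator_corrections"]

#: Source-to-collimator distance of the insert holding the modulator (cm).
COLLIMATOR_PLANE_CM = 93.5

#: Machinable foam density recorded for provenance only; the energy-loss
#: correction is applied as a rigid 0.1 cm shift of the falloff, not by
#: transporting through the foam explicitly.
FOAM_DENSITY_G_CM3 = 0.096

_PDD_STEP_CM = 0.02


@dataclass(frozen=True)
class BeamModel:
    """A matched electron beam.

    Attributes
    ----------
    nominal_energy : float
        Nominal beam energy in MeV.
    r100, r90, rp : float
        Depth of maximum dose, therapeutic range (90%) and practical range,
        all in cm of water.
    depths, percents : ndarray
        Tabulated central-axis percent depth dose (depth cm, percent).
    sigma_theta0 : float
        Initial angular spread of the beam in radians; drives the in-air
        Gaussian spread of each pencil between collimator and surface.
    xray_tail : float
        Bremsstrahlung background level beyond ``rp``, percent of given dose.
    virtual_source_to_isocenter : float
        Distance from the virtual electron point source to isocenter (cm).
    mcs_k : float
        Scattering-power constant of the Fermi-Eyges accumulation,
        calibrated at construction (see :meth:`sigma_mcs`).
    """

    nominal_energy: float
    r100: float
    r90: float
    rp: float
    depths: np.ndarray
    percents: np.ndarray
    sigma_theta0: float
    xray_tail: float
    virtual_source_to_isocenter: float = 100.0
    mcs_k: float = field(default=0.0)

    def pdd(self, depth):
        """Percent depth dose at ``depth`` cm (scalar or array).

        Linear interpolation of the tabulated curve; beyond the last table
        entry the constant x-ray tail is returned.  Negative depths raise
        ``ValueError``.
        """
        d = np.asarray(depth, dtype=float)
        if np.any(d < 0):
            raise ValueError("depth must be non-negative")
        out = np.interp(d, self.depths, self.percents, right=self.xray_tail)
        return float(out) if np.isscalar(depth) else out

    def depth_of_percent(self, percent: float) -> float:
        """Depth of the distal (falloff-side) crossing of ``percent``."""
        if not (self.xray_tail < percent <= 100.0):
            raise ValueError("percent must lie between the x-ray tail and 100")
        sel = self.depths >= self.r100
        d, p = self.depths[sel], self.percents[sel]
        # p is monotone non-increasing beyond R100
        return float(np.interp(-percent, -p, d))

    def electron_percent(self, depth):
        """Electron component of the PDD: total minus the ramped x-ray part."""
        return np.maximum(self.pdd(depth) - self.xray_background(depth), 0.0)

    def xray_background(self, depth):
        """Ramped x-ray background: tail * min(depth / Rp, 1)."""
        d = np.asarray(depth, dtype=float)
        return self.xray_tail * np.minimum(d / self.rp, 1.0)

    def sigma_air(self, surface_z: float, modulated: bool = False) -> float:
        """In-air Gaussian pencil spread at plane ``surface_z`` (cm from source).

        ``sigma = sigma_theta0 * (surface_z - collimator_z)``; island-block
        deficits are transported with the modulator-corrected spread
        (``modulated=True``, factor 1.5).
        """
        factor = 1.5 if modulated else 1.0
        return factor * self.sigma_theta0 * max(surface_z - COLLIMATOR_PLANE_CM, 0.0)

    def sigma_mcs(self, depth):
        """RMS lateral spread from multiple Coulomb scattering at water depth.

        Fermi-Eyges accumulation ``sigma^2(d) = k * I(d)`` with
        ``I(d) = int_0^d (d-t)^2 / (1 - t/Rp)^2 dt`` (linear energy loss,
        scattering power ~ 1/E^2); ``k`` is calibrated at construction so
        that ``sigma(R90/2)`` equals the calibration value supplied at
        construction (default 0.45 cm, representative of a 16 MeV beam).
        """
        d = np.atleast_1d(np.asarray(depth, dtype=float))
        out = np.sqrt(self.mcs_k * _mcs_integral(d, self.rp))
        return float(out[0]) if np.isscalar(depth) else out


def _mcs_integral(d: np.ndarray, rp: float) -> np.ndarray:
    """``int_0^d (d-t)^2 / max(1 - t/Rp, eps)^2 dt`` elementwise (vectorised)."""
    # closed form for u = 1 - t/rp clipped at eps to keep the integrand finite
    eps = 0.05
    out = np.empty_like(d)
    for i, di in enumerate(d.ravel()):
        val, _ = quad(
            lambda t, di=di: (di - t) ** 2 / max(1.0 - t / rp, eps) ** 2,
            0.0,
            max(di, 0.0),
            limit=100,
        )
        out.ravel()[i] = val
    return out


def _falloff_exponent(r100: float, r90: float, rp: float, tail: float) -> float:
    """Exponent p of the falloff g(s) = (1 + cos(pi s^p))/2 with g(s90) pinned."""
    s90 = (r90 - r100) / (rp - r100)
    target = (90.0 - tail) / (100.0 - tail)

    def f(p):
        return 0.5 * (1.0 + np.cos(np.pi * s90**p)) - target

    return brentq(f, 0.05, 50.0)


def make_beam(
    r90: float,
    nominal_energy: float,
    *,
    sigma_theta0: float = 0.03,
    xray_tail: float = 3.0,
    surface_dose: float = 85.0,
    sigma_mcs_half_r90: float = 0.45,
) -> BeamModel:
    """Build an analytic beam model from its therapeutic range and energy.

    ``R100 = 0.6 * R90`` and ``Rp = 0.5 * E`` (cm, E in MeV) — standard rules
    of thumb; the PDD is then constructed to satisfy ``pdd(R100) = 100``,
    ``pdd(R90) = 90`` and a constant x-ray tail beyond ``Rp``.

    Parameters
    ----------
    r90 : float
        Therapeutic range in cm; must exceed 0.5 cm.
    nominal_energy : float
        Nominal energy in MeV; sets the practical range.
    sigma_theta0 : float, optional
        Initial angular spread in radians (default 0.03 rad).  The
        unmodulated spread of a specific accelerator is commissioning data;
        override it from the beam config block when known.
    xray_tail : float, optional
        Bremsstrahlung tail as percent of given dose (default 3.0).
    surface_dose : float, optional
        Percent dose at zero depth (default 85).
    sigma_mcs_half_r90 : float, optional
        Calibration of the Fermi-Eyges scattering constant: the rms lateral
        spread, in cm, that a pencil accumulates by the depth ``R90/2``
        (default 0.45 cm, representative of a 16 MeV clinical beam).
    """
    if not np.isfinite(r90) or r90 <= 0.5:
        raise ValueError("r90 must be a positive depth greater than 0.5 cm")
    if not (0.0 < xray_tail < 10.0):
        raise ValueError("xray_tail must lie in (0, 10) percent")
    r100 = 0.6 * r90
    rp = 0.5 * nominal_energy
    if not r100 < r90 < rp:
        raise ValueError(
            f"inconsistent ranges (R100={r100:.2f}, R90={r90:.2f}, Rp={rp:.2f}); "
            "increase nominal_energy or reduce r90"
        )
    if not (0.0 < surface_dose < 100.0):
        raise ValueError("surface_dose must lie in (0, 100) percent")

    depths = np.arange(0.0, rp + 2.0 + _PDD_STEP_CM, _PDD_STEP_CM)
    # pin the anchor depths to exact table nodes
    depths = np.union1d(depths, [r100, r90, rp])
    p_exp = _falloff_exponent(r100, r90, rp, xray_tail)
    percents = np.empty_like(depths)

    build = depths <= r100
    percents[build] = 100.0 - (100.0 - surface_dose) * (1.0 - depths[build] / r100) ** 2

    fall = (depths > r100) & (depths <= rp)
    s = (depths[fall] - r100) / (rp - r100)
    percents[fall] = xray_tail + (100.0 - xray_tail) * 0.5 * (1.0 + np.cos(np.pi * s**p_exp))

    percents[depths > rp] = xray_tail

    i_half = _mcs_integral(np.array([r90 / 2.0]), rp)[0]
    mcs_k = sigma_mcs_half_r90**2 / i_half

    return BeamModel(
        nominal_energy=float(nominal_energy),
        r100=r100,
        r90=float(r90),
        rp=rp,
        depths=depths,
        percents=percents,
        sigma_theta0=float(sigma_theta0),
        xray_tail=float(xray_tail),
        mcs_k=mcs_k,
    )


def apply_modulator_corrections(beam: BeamModel) -> BeamModel:
    """Return a copy of ``beam`` corrected for the modulator foam.

    The depth-dose curve is shifted rigidly 0.1 cm shallower (energy loss in
    the foam insert: R90, R100 and Rp all decrease by 0.1 cm) and the initial
    angular spread increases by 50% (extra foam scatter).  The operation is
    intentionally not idempotent: applying it twice models two foam slabs
    (R90 down 0.2 cm, spread x2.25).
    """
    shift = 0.1
    new_depths = beam.depths - shift
    keep = new_depths >= 0.0
    depths = np.concatenate(([0.0], new_depths[keep])) if new_depths[0] < 0 else new_depths
    percents = (
        np.concatenate(([np.interp(shift, beam.depths, beam.percents)], beam.percents[keep]))
        if new_depths[0] < 0
        else beam.percents
    )
    return replace(
        beam,
        r100=beam.r100 - shift,
        r90=beam.r90 - shift,
        rp=beam.rp - shift,
        depths=depths,
        percents=percents,
        sigma_theta0=1.5 * beam.sigma_theta0,
    )
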