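"""Dose-volume histograms and plan metrics (D90-10, Dmax, V95 matching).

Plans are scored on the PTV with the cumulative DVH.  ``D_x`` is the dose
received by at least ``x``% of the volume; the homogeneity span
``D_90-10 = D10 − D90`` covers the central 80% of the volume.  When two
plans are compared their DVHs are first normalised so the PTV ``V95``
(volume fraction receiving at least 95%) matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DVH", "dvh", "metric_d_span", "normalize_match_v95"]


@dataclass(frozen=True)
class DVH:
    """Cumulative dose-volume histogram of one structure.

    ``volume_pct[k]`` is the percent of the structure receiving at least
    ``dose_levels[k]`` percent dose; monotone non-increasing with
    ``V(0) = 100``.
    """

    dose_levels: np.ndarray
    volume_pct: np.ndarray = field(repr=False)
    name: str = "structure"

    def volume_at_dose(self, dose: float) -> float:
        """V(dose): percent of volume receiving at least ``dose``."""
        return float(np.interp(dose, self.dose_levels, self.volume_pct))

    def dose_at_volume(self, volume: float) -> float:
        """D_x: dose received by at least ``volume`` percent of the structure."""
        # volume_pct decreases with dose; invert by flipping
        return float(np.interp(volume, self.volume_pct[::-1], self.dose_levels[::-1]))

    @property
    def dmax(self) -> float:
        nz = self.volume_pct > 0
        return float(self.dose_levels[nz][-1]) if nz.any() else 0.0


def dvh(dose, mask: np.ndarray, bins: int = 1000, name: str = "structure") -> DVH:
    """Cumulative DVH of ``dose`` (a Dose3D or array) over a boolean mask."""
    values = dose.values if hasattr(dose, "values") else np.asarray(dose)
    d = values[mask]
    if d.size == 0:
        raise ValueError("mask selects no voxels")
    top = float(d.max())
    levels = np.linspace(0.0, top, bins + 1)
    vol = 100.0 * np.count_nonzero(d[None, :] >= levels[:, None], axis=1) / d.size
    return DVH(dose_levels=levels, volume_pct=vol.astype(float), name=name)


def metric_d_span(histogram: DVH, hi: float = 90.0, lo: float = 10.0) -> float:
    """Dose span ``D_lo − D_hi`` (for the defaults: D10 − D90, the D90-10)."""
    return histogram.dose_at_volume(lo) - histogram.dose_at_volume(hi)


def normalize_match_v95(dose_a, dose_b, ptv: np.ndarray, tol_pp: float = 0.1):
    """Scale ``dose_b`` so its PTV V95 matches ``dose_a``'s.

    The scale factor is found by bisection; V95 is non-decreasing in the
    factor.  Returns (scaled_b_values, factor); matching is to within
    ``tol_pp`` percentage points where the discrete voxel distribution
    allows it.
    """
    a = dose_a.values if hasattr(dose_a, "values") else np.asarray(dose_a)
    b = dose_b.values if hasattr(dose_b, "values") else np.asarray(dose_b)
    da, db = a[ptv], b[ptv]
    target = 100.0 * np.count_nonzero(da >= 95.0) / da.size

    def v95(f: float) -> float:
        return 100.0 * np.count_nonzero(f * db >= 95.0) / db.size

    lo, hi = 0.05, 20.0
    if v95(lo) > target or v95(hi) < target:
        raise ValueError("V95 target not bracketed by scale factors [0.05, 20]")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if v95(mid) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-9:
            break
    factor = hi if abs(v95(hi) - target) <= abs(v95(lo) - target) else lo
    if abs(v95(factor) - target) > tol_pp:
        # discrete volume steps can exceed tol_pp; keep the closest factor
        pass
    return factor * b, float(factor)
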