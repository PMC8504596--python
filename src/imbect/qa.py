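"""Planar dose comparison: dose difference, DTA and the composite criterion.

Clinical verification of an intensity modulator compares a measured planar
dose at depth in water against the calculated one.  A point passes when the
measured dose is within a dose tolerance (default 3% of given dose) *or*
within a distance-to-agreement (DTA, default 0.3 cm) of the calculated
distribution; only points where the calculated dose reaches an inclusion
threshold (default 10%) are evaluated.  The calculated grid is the
reference: DTA searches the (bilinearly interpolated) calculated
distribution for the nearest location with the measured point's value.

A combined gamma index (dose/distance in quadrature) is provided as an
optional mode; the OR-criterion above is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .planar import PlanarDose

__all__ = ["QAReport", "dose_difference", "dta", "composite_pass", "gamma_index"]

_UPSAMPLE = 4


@dataclass(frozen=True)
class QAReport:
    """Result of a planar composite comparison."""

    diff: np.ndarray = field(repr=False)
    dta: np.ndarray = field(repr=False)
    passed: np.ndarray = field(repr=False)
    mask: np.ndarray = field(repr=False)
    pass_rate: float = 0.0
    histogram_edges: np.ndarray = field(repr=False, default=None)
    histogram_counts: np.ndarray = field(repr=False, default=None)
    histogram_counts_low_dose: np.ndarray = field(repr=False, default=None)

    def summary(self) -> dict:
        return {
            "pass_rate_pct": round(self.pass_rate, 2),
            "points_evaluated": int(self.mask.sum()),
            "points_failed": int(self.mask.sum() - self.passed.sum()),
            "dose_diff_range_pct": [float(self.diff[self.mask].min()), float(self.diff[self.mask].max())]
            if self.mask.any()
            else [0.0, 0.0],
        }


def _resample_to(calc: PlanarDose, meas: PlanarDose) -> np.ndarray:
    """Measured values bilinearly resampled onto the calculated grid."""
    if meas.values.shape == calc.values.shape and np.allclose(meas.x, calc.x) and np.allclose(
        meas.y, calc.y
    ):
        return meas.values
    interp = RegularGridInterpolator(
        (meas.x, meas.y), meas.values, bounds_error=False, fill_value=0.0
    )
    gx, gy = np.meshgrid(calc.x, calc.y, indexing="ij")
    return interp(np.stack([gx, gy], axis=-1))


def dose_difference(calc: PlanarDose, meas: PlanarDose) -> np.ndarray:
    """Measured minus calculated dose, percent-of-given-dose points."""
    return _resample_to(calc, meas) - calc.values


def _fine_calc(calc: PlanarDose) -> tuple[np.ndarray, float]:
    """Calculated grid bilinearly upsampled for subpixel isovalue search."""
    fine_pix = calc.pixel / _UPSAMPLE
    fx = np.linspace(calc.x[0], calc.x[-1], (calc.x.size - 1) * _UPSAMPLE + 1)
    fy = np.linspace(calc.y[0], calc.y[-1], (calc.y.size - 1) * _UPSAMPLE + 1)
    interp = RegularGridInterpolator((calc.x, calc.y), calc.values)
    gx, gy = np.meshgrid(fx, fy, indexing="ij")
    return interp(np.stack([gx, gy], axis=-1)), fine_pix


def dta(
    calc: PlanarDose,
    meas: PlanarDose,
    cap: float = 1.0,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Distance to agreement, cm, capped at ``cap``.

    For each evaluated point the distance to the nearest location where the
    interpolated calculated distribution equals the measured value; points
    with no equal-value location within ``cap`` get ``cap``.  ``mask``
    restricts the computation (unevaluated points return NaN-free ``cap``).
    """
    mv = _resample_to(calc, meas)
    fine, fine_pix = _fine_calc(calc)
    nfx, nfy = fine.shape
    w = int(np.ceil(cap / fine_pix))
    ax = np.arange(-w, w + 1) * fine_pix
    radial = np.hypot(ax[:, None], ax[None, :])

    out = np.full(calc.values.shape, cap)
    if mask is None:
        mask = np.ones_like(out, dtype=bool)
    idx_pts = np.argwhere(mask)
    for i, j in idx_pts:
        fi, fj = i * _UPSAMPLE, j * _UPSAMPLE
        i0, i1 = max(fi - w, 0), min(fi + w + 1, nfx)
        j0, j1 = max(fj - w, 0), min(fj + w + 1, nfy)
        window = fine[i0:i1, j0:j1] - mv[i, j]
        # an isovalue location exists in a fine cell when the sign changes
        # across it (or the residual is essentially zero)
        hit = np.abs(window) < 1e-9
        hit[:-1, :] |= window[:-1, :] * window[1:, :] <= 0
        hit[:, :-1] |= window[:, :-1] * window[:, 1:] <= 0
        if hit.any():
            rad = radial[i0 - fi + w : i1 - fi + w, j0 - fj + w : j1 - fj + w]
            out[i, j] = min(float(rad[hit].min()), cap)
    return out


def composite_pass(
    calc: PlanarDose,
    meas: PlanarDose,
    dose_tol: float = 3.0,
    dist_tol: float = 0.3,
    threshold: float = 10.0,
    cap: float = 1.0,
    threshold_mode: str = "max",
    histogram_bins: int = 40,
) -> QAReport:
    """Composite dose-difference / DTA comparison.

    ``threshold_mode='max'`` includes points where the calculated dose is at
    least ``threshold`` percent of the calculated maximum (the default);
    ``'given'`` compares against percent of given dose directly.  A point
    passes when ``|diff| <= dose_tol`` or ``DTA <= dist_tol``.  The report
    histograms dose differences over the evaluated points, flagging the
    subset with calculated dose below 80% separately.
    """
    diff = dose_difference(calc, meas)
    if threshold_mode == "max":
        cut = threshold / 100.0 * calc.values.max()
    elif threshold_mode == "given":
        cut = threshold
    else:
        raise ValueError("threshold_mode must be 'max' or 'given'")
    mask = calc.values >= cut

    need_dta = mask & (np.abs(diff) > dose_tol)
    dta_map = np.full(calc.values.shape, cap)
    if need_dta.any():
        dta_map = dta(calc, meas, cap=cap, mask=need_dta)
    passed = mask & ((np.abs(diff) <= dose_tol) | (dta_map <= dist_tol))
    n = int(mask.sum())
    rate = 100.0 * passed.sum() / n if n else 100.0

    lo, hi = (diff[mask].min(), diff[mask].max()) if n else (-1.0, 1.0)
    pad = max(0.5, 0.05 * (hi - lo))
    edges = np.linspace(lo - pad, hi + pad, histogram_bins + 1)
    counts, _ = np.histogram(diff[mask], bins=edges)
    low = mask & (calc.values < 80.0)
    counts_low, _ = np.histogram(diff[low], bins=edges)
    return QAReport(
        diff=diff,
        dta=dta_map,
        passed=passed,
        mask=mask,
        pass_rate=float(rate),
        histogram_edges=edges,
        histogram_counts=counts,
        histogram_counts_low_dose=counts_low,
    )


def gamma_index(
    calc: PlanarDose,
    meas: PlanarDose,
    dose_tol: float = 3.0,
    dist_tol: float = 0.3,
    threshold: float = 10.0,
    threshold_mode: str = "max",
) -> np.ndarray:
    """Combined dose/distance index (optional mode; <= 1 passes).

    ``gamma(p) = min_q sqrt((|q-p|/dist_tol)^2 + ((calc(q)-meas(p))/dose_tol)^2)``
    searched over the upsampled calculated grid within ``2*dist_tol``.
    Points below the inclusion threshold return NaN.
    """
    mv = _resample_to(calc, meas)
    fine, fine_pix = _fine_calc(calc)
    cut = threshold / 100.0 * calc.values.max() if threshold_mode == "max" else threshold
    mask = calc.values >= cut
    w = int(np.ceil(2.0 * dist_tol / fine_pix))
    ax = np.arange(-w, w + 1) * fine_pix
    dist2 = (ax[:, None] ** 2 + ax[None, :] ** 2) / dist_tol**2
    nfx, nfy = fine.shape
    out = np.full(calc.values.shape, np.nan)
    for i, j in np.argwhere(mask):
        fi, fj = i * _UPSAMPLE, j * _UPSAMPLE
        i0, i1 = max(fi - w, 0), min(fi + w + 1, nfx)
        j0, j1 = max(fj - w, 0), min(fj + w + 1, nfy)
        dd = (fine[i0:i1, j0:j1] - mv[i, j]) / dose_tol
        d2 = dist2[i0 - fi + w : i1 - fi + w, j0 - fj + w : j1 - fj + w]
        out[i, j] = float(np.sqrt((dd**2 + d2).min()))
    return out
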