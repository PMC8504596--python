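"""Electron fluence transport from the collimator to the phantom surface.

The planning lattice is a grid of fan lines: diverging rays from the virtual
source through regularly spaced points of the isocenter plane, each carrying
a dimensionless pencil weight (1 inside the aperture, 0 outside; intensity
modulation multiplies the weights by the intensity reduction factor).

Transport to a downstream plane spreads each pencil by an in-air Gaussian of
width ``sigma_theta * (z - z_collimator)``.  A passive intensity modulator
removes electrons with its tungsten island blocks; under the
perfect-collimation assumption every electron incident on a block's top face
is lost, so each circular block is modelled as a *negative* square pencil of
equal area (side ``d * sqrt(pi)/2``) transported with the modulator-corrected
angular spread (1.5x) and subtracted from the open-field fluence.  Negative
results after summation are clamped to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from scipy.ndimage import gaussian_filter, map_coordinates

from .beam import BeamModel
from .geometry import ISOCENTER_Z_CM, Aperture

__all__ = ["FanLineGrid", "SurfaceFluence", "fan_grid_for_aperture", "transport_fluence"]


@dataclass(frozen=True)
class FanLineGrid:
    """Fan-line lattice: positions in the isocenter plane plus pencil weights."""

    x: np.ndarray
    y: np.ndarray
    weights: np.ndarray = field(repr=False)
    spacing: float = 0.2

    def __post_init__(self):
        if self.weights.shape != (self.x.size, self.y.size):
            raise ValueError("weights shape must be (len(x), len(y))")
        if np.any(self.weights < 0):
            raise ValueError("pencil weights must be non-negative")

    def with_weights(self, weights: np.ndarray) -> "FanLineGrid":
        return replace(self, weights=np.asarray(weights, dtype=float))


def fan_grid_for_aperture(
    aperture: Aperture, spacing: float = 0.2, margin: float = 2.0
) -> FanLineGrid:
    """Fan-line grid covering the aperture bounding box plus ``margin`` cm.

    Unmodulated weights: 1 for fan lines inside the aperture, 0 outside
    (the penumbra arises from Gaussian spreading, not from the weights).
    """
    xmin, ymin, xmax, ymax = aperture.bounding_box()
    x = _centered_axis(xmin - margin, xmax + margin, spacing)
    y = _centered_axis(ymin - margin, ymax + margin, spacing)
    inside = aperture.contains_points(
        np.repeat(x, y.size), np.tile(y, x.size)
    ).reshape(x.size, y.size)
    return FanLineGrid(x=x, y=y, weights=inside.astype(float), spacing=spacing)


def _centered_axis(lo: float, hi: float, step: float) -> np.ndarray:
    """Symmetric lattice containing 0 that spans [lo, hi]."""
    n_lo = int(np.ceil(-lo / step))
    n_hi = int(np.ceil(hi / step))
    return np.arange(-n_lo, n_hi + 1) * step


@dataclass(frozen=True)
class SurfaceFluence:
    """Relative fluence maps at the bolus/phantom entrance plane.

    ``values`` includes the island-block deficits (clamped at zero);
    ``open_values`` is the same beam without blocks, used for normalisation
    and for the unblocked x-ray background.  Coordinates are in the surface
    plane ``z = surface_z``.
    """

    x: np.ndarray
    y: np.ndarray
    values: np.ndarray = field(repr=False)
    open_values: np.ndarray = field(repr=False)
    surface_z: float = 100.0

    @property
    def pixel(self) -> float:
        return float(self.x[1] - self.x[0])


def _rasterize_square(
    deficit: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    cx: float,
    cy: float,
    side: float,
    amplitude: float,
) -> None:
    """Add an axis-aligned square of exact fractional pixel coverage.

    The overlap of the square with each pixel is separable in x and y, so
    the deposited integral equals ``amplitude * side**2`` exactly regardless
    of pixel size — Gaussian spreading then conserves it.
    """
    px = x[1] - x[0]
    h = side / 2.0
    fx = np.clip((np.minimum(x + px / 2, cx + h) - np.maximum(x - px / 2, cx - h)) / px, 0.0, 1.0)
    fy = np.clip((np.minimum(y + px / 2, cy + h) - np.maximum(y - px / 2, cy - h)) / px, 0.0, 1.0)
    ix = np.nonzero(fx)[0]
    iy = np.nonzero(fy)[0]
    if ix.size == 0 or iy.size == 0:
        return
    deficit[np.ix_(ix, iy)] += amplitude * np.outer(fx[ix], fy[iy])


def transport_fluence(
    fan: FanLineGrid,
    aperture: Aperture | None,
    blocks,
    beam: BeamModel,
    surface_z: float,
    pixel: float | None = None,
) -> SurfaceFluence:
    """Transport the collimated, optionally modulated beam to a plane.

    Parameters
    ----------
    fan : FanLineGrid
        Pencil weights in the isocenter plane.  When ``aperture`` is given
        the weights are additionally collimated by it; passing ``None``
        relies on the zeros already present in the weights.
    blocks : IslandBlockPattern or None
        Island-block pattern in the collimator plane; ``None`` means an
        unmodulated beam (the block sum is empty and the result equals the
        open field exactly).
    surface_z : float
        Plane of the bolus/phantom surface, cm from the virtual source;
        must lie beyond the collimator plane.
    pixel : float, optional
        Output pixel at the surface plane.  Default: the fan spacing
        projected to the surface plane.

    Returns
    -------
    SurfaceFluence
        Modulated and open-field relative fluence on the surface-plane grid.
    """
    z_col = aperture.collimator_z if aperture is not None else 93.5
    if surface_z <= z_col:
        raise ValueError("surface plane must be downstream of the collimator")
    scale = surface_z / ISOCENTER_Z_CM
    if pixel is None:
        pixel = fan.spacing * scale

    weights = fan.weights
    if aperture is not None:
        inside = aperture.contains_points(
            np.repeat(fan.x, fan.y.size), np.tile(fan.y, fan.x.size)
        ).reshape(weights.shape)
        weights = weights * inside

    # surface-plane grid covering the projected fan lattice
    x = _centered_axis(fan.x[0] * scale, fan.x[-1] * scale, pixel)
    y = _centered_axis(fan.y[0] * scale, fan.y[-1] * scale, pixel)

    # open beam: weights sampled at the projected fan positions, spread in air
    wx = np.interp(x / scale, fan.x, np.arange(fan.x.size))
    wy = np.interp(y / scale, fan.y, np.arange(fan.y.size))
    gx, gy = np.meshgrid(wx, wy, indexing="ij")
    open_raw = map_coordinates(weights, [gx, gy], order=1, mode="nearest")
    sigma_open = beam.sigma_air(surface_z, modulated=False)
    open_vals = gaussian_filter(open_raw, sigma=sigma_open / pixel, mode="nearest")

    values = open_vals.copy()
    if blocks is not None and len(blocks) > 0:
        deficit = np.zeros_like(open_vals)
        block_scale = surface_z / blocks.plane
        ap_poly = aperture.polygon_at(blocks.plane) if aperture is not None else None
        for bx, by, d in blocks.pins():
            if ap_poly is not None and not ap_poly.contains(shapely.Point(bx, by)):
                warnings.warn(
                    f"island block at ({bx:.2f}, {by:.2f}) lies outside the aperture",
                    stacklevel=2,
                )
            side = d * np.sqrt(np.pi) / 2.0 * block_scale
            cx, cy = bx * block_scale, by * block_scale
            w_local = float(
                map_coordinates(
                    weights,
                    [
                        [np.interp(cx / scale, fan.x, np.arange(fan.x.size))],
                        [np.interp(cy / scale, fan.y, np.arange(fan.y.size))],
                    ],
                    order=1,
                    mode="nearest",
                )[0]
            )
            _rasterize_square(deficit, x, y, cx, cy, side, w_local)
        sigma_block = beam.sigma_air(surface_z, modulated=True)
        values = open_vals - gaussian_filter(deficit, sigma=sigma_block / pixel, mode="nearest")
        np.clip(values, 0.0, None, out=values)

    return SurfaceFluence(x=x, y=y, values=values, open_values=open_vals, surface_z=surface_z)
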