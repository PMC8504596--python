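"""2D planar maps (dose, thickness, IRF) and their plain-text dialect.

A single ASCII format is shared by planar QA dose grids, bolus height maps
and intensity maps.  Layout::

    # imbect-planar 1
    field: dose_pct
    depth_cm: 2.0
    ssd_cm: 100.0
    pixel_cm: 0.1
    nx: 141
    ny: 141
    origin_x_cm: -7.0
    origin_y_cm: -7.0
    <nx rows of ny whitespace-separated values, row-major in x>

``origin`` refers to the center of the first pixel; values are percent of
given dose for ``dose_pct``, cm for ``thickness_cm``, dimensionless for
``irf``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["PlanarDose", "write_planar", "read_planar"]

_MAGIC = "# imbect-planar 1"


@dataclass(frozen=True)
class PlanarDose:
    """2D percent-dose grid at a stated depth in water.

    ``values[ix, iy]`` on a square-pixel lattice; ``x``/``y`` are the pixel
    center coordinates in the measurement plane.
    """

    x: np.ndarray
    y: np.ndarray
    values: np.ndarray = field(repr=False)
    depth: float = 0.0
    ssd: float = 100.0

    def __post_init__(self):
        if self.values.shape != (self.x.size, self.y.size):
            raise ValueError("values shape must be (len(x), len(y))")
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("planar dose must be finite and non-negative")

    @property
    def pixel(self) -> float:
        return float(self.x[1] - self.x[0])


def write_planar(path, planar: PlanarDose, field_name: str = "dose_pct") -> None:
    """Write a planar map in the shared ASCII dialect."""
    lines = [
        _MAGIC,
        f"field: {field_name}",
        f"depth_cm: {planar.depth:g}",
        f"ssd_cm: {planar.ssd:g}",
        f"pixel_cm: {planar.pixel:.6g}",
        f"nx: {planar.x.size}",
        f"ny: {planar.y.size}",
        f"origin_x_cm: {planar.x[0]:.6g}",
        f"origin_y_cm: {planar.y[0]:.6g}",
    ]
    body = "\n".join(" ".join(f"{v:.6g}" for v in row) for row in planar.values)
    Path(path).write_text("\n".join(lines) + "\n" + body + "\n")


def read_planar(path) -> tuple[PlanarDose, str]:
    """Read a planar map; returns the map and its field name."""
    text = Path(path).read_text().splitlines()
    if not text or text[0].strip() != _MAGIC:
        raise ValueError(f"{path}: not an imbect planar file")
    header: dict[str, str] = {}
    i = 1
    while i < len(text) and ":" in text[i]:
        key, _, val = text[i].partition(":")
        header[key.strip()] = val.strip()
        i += 1
    nx, ny = int(header["nx"]), int(header["ny"])
    pixel = float(header["pixel_cm"])
    values = np.loadtxt(text[i:]).reshape(nx, ny)
    x0, y0 = float(header["origin_x_cm"]), float(header["origin_y_cm"])
    planar = PlanarDose(
        x=x0 + pixel * np.arange(nx),
        y=y0 + pixel * np.arange(ny),
        values=values,
        depth=float(header.get("depth_cm", 0.0)),
        ssd=float(header.get("ssd_cm", 100.0)),
    )
    return planar, header.get("field", "dose_pct")
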