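"""Pin-pattern CSV interchange (the fabrication hand-off file).

One row per pin: ``x_cm, y_cm, diameter_cm``, coordinates in the modulator
plane (93.5 cm from the source).  The reader validates that every pin sits
on the hexagonal lattice and that every diameter comes from the catalog.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .segmentation import IslandBlockPattern, PinCatalog

__all__ = ["write_pin_pattern", "read_pin_pattern"]

_TOL = 1e-6


def write_pin_pattern(path, pattern: IslandBlockPattern) -> None:
    rows = [(x, y, d) for x, y, d in pattern.pins()]
    df = pd.DataFrame(rows, columns=["x_cm", "y_cm", "diameter_cm"])
    df.to_csv(path, index=False, float_format="%.6g")


def _on_lattice(x: np.ndarray, y: np.ndarray, r: float) -> bool:
    hy = r * np.sqrt(3.0) / 2.0
    k = y / hy
    if not np.allclose(k, np.round(k), atol=1e-4):
        return False
    off = (np.abs(np.round(k)).astype(int) % 2) * r / 2.0
    j = (x - off) / r
    return bool(np.allclose(j, np.round(j), atol=1e-4))


def read_pin_pattern(path, catalog: PinCatalog | None = None) -> IslandBlockPattern:
    """Read and validate a pin CSV; raises ``ValueError`` on violations."""
    catalog = catalog or PinCatalog()
    df = pd.read_csv(path)
    required = {"x_cm", "y_cm", "diameter_cm"}
    if not required.issubset(df.columns):
        raise ValueError(f"pin file must have columns {sorted(required)}")
    x = df["x_cm"].to_numpy(float)
    y = df["y_cm"].to_numpy(float)
    d = df["diameter_cm"].to_numpy(float)
    allowed = np.asarray(catalog.diameters)
    if d.size and not np.all(np.isclose(d[:, None], allowed[None, :], atol=_TOL).any(axis=1)):
        raise ValueError("pin diameters must come from the catalog")
    if d.size and not _on_lattice(x, y, catalog.r):
        raise ValueError(f"pin centers must lie on the {catalog.r} cm hexagonal lattice")
    sites = np.column_stack([x, y]) if d.size else np.empty((0, 2))
    return IslandBlockPattern(sites=sites, diameters=d, catalog=catalog)
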