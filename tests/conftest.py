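import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import imbect as ib

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def beam():
    """The study beam: 16 MeV, R90 = 5.0 cm."""
    return ib.make_beam(5.0, 16)


@pytest.fixture(scope="session")
def aperture():
    return ib.rectangular_aperture(10.0, 10.0)


@pytest.fixture(scope="session")
def water_grid():
    return ib.water_tank((14.0, 14.0, 8.0), (0.2, 0.2, 0.2), 100.0)


@pytest.fixture(scope="session")
def wavy():
    """Default wavy-slab phantom (grid, ptv)."""
    return ib.wavy_slab_phantom()


@pytest.fixture(scope="session")
def fan_for(aperture, water_grid):
    """Fan grid aligned with the water grid lattice, collimated by the aperture."""
    g = water_grid
    inside = aperture.contains_points(
        np.repeat(g.x, g.y.size), np.tile(g.y, g.x.size)
    ).reshape(g.x.size, g.y.size)
    return ib.FanLineGrid(x=g.x, y=g.y, weights=inside.astype(float), spacing=0.2)


def bect_sequence(n_shift: int = 2, final_delta: float = -0.1):
    """Conformal-bolus operator sequence in the clinical vocabulary."""
    seq = [("create", {"percent": 90, "inner_margin": 0.7}),
           ("smooth", {"exp_mult": 2, "radius_mult": 1})]
    for _ in range(n_shift):
        seq += [("isodose_shift", {"inner_margin": 0.5}),
                ("smooth", {"exp_mult": 2, "radius_mult": 1})]
    seq += [("truncate", {})]
    if final_delta is not None:
        seq += [("specified_shift", {"delta": final_delta})]
    return seq


def im_bect_sequence(n_shift: int = 2):
    """BECT sequence plus intensity modulation and bolus reoptimisation."""
    return bect_sequence(n_shift) + [
        ("intensity_modulation", {"margin": 0.5}),
        ("isodose_shift", {"inner_margin": 0.5}),
        ("smooth", {"exp_mult": 2, "radius_mult": 1}),
        ("specified_shift", {"delta": -0.1}),
    ]
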