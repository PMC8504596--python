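import dataclasses

import numpy as np
import pytest

import imbect as ib
from imbect.bolus import (
    BolusSurface,
    conformality,
    depth_of_90,
    distal_ptv_depth,
    eroded_ptv_projection,
    op_create,
    op_height_extension,
    op_isodose_shift,
    op_smooth,
    op_specified_shift,
    op_truncate,
    run_sequence,
)
from tests.conftest import bect_sequence


def flat_bolus(grid, value=1.0):
    t = np.full((grid.x.size, grid.y.size), value)
    return BolusSurface(x=grid.x, y=grid.y, thickness=t)


class TestCreate:
    def test_flat_slab_physical_depth_rule(self, beam):
        """Distal PTV at 3.0 cm water depth, R90 5.0, unit density -> t = 2.0."""
        grid, ptv = ib.wavy_slab_phantom(0.0, 8.0)
        b = op_create(ptv, grid, beam, percent=90, inner_margin=0.7, density=1.0)
        el = eroded_ptv_projection(ptv, grid, 0.7)
        assert np.allclose(b.thickness[el], 2.0, atol=0.11)

    def test_distal_at_r90_gives_zero_thickness(self, beam):
        grid, ptv = ib.wavy_slab_phantom(0.0, 8.0, ptv_distal_depth=5.0, extent=(14, 14, 7))
        b = op_create(ptv, grid, beam, density=1.0)
        el = eroded_ptv_projection(ptv, grid, 0.7)
        assert np.all(b.thickness[el] <= 0.11)

    def test_thickness_anticorrelates_with_distal_depth(self, beam):
        grid, ptv = ib.wavy_slab_phantom(0.75, 8.0)
        b = op_create(ptv, grid, beam, density=1.0)
        el = eroded_ptv_projection(ptv, grid, 0.7)
        zd = distal_ptv_depth(ptv, grid)
        corr = np.corrcoef(b.thickness[el], zd[el])[0, 1]
        assert corr < -0.99
        assert np.ptp(b.thickness[el]) == pytest.approx(2 * 0.75, abs=0.25)

    def test_deterministic(self, beam):
        grid, ptv = ib.wavy_slab_phantom()
        b1 = op_create(ptv, grid, beam)
        b2 = op_create(ptv, grid, beam)
        assert np.array_equal(b1.thickness, b2.thickness)

    def test_empty_ptv_rejected(self, beam, water_grid):
        with pytest.raises(ValueError):
            op_create(np.zeros(water_grid.shape, dtype=bool), water_grid, beam)


class TestSmooth:
    def test_uniform_bolus_unchanged(self, water_grid):
        b = flat_bolus(water_grid, 1.5)
        s = op_smooth(b, 2, 1)
        assert np.allclose(s.thickness, 1.5, atol=1e-9)

    def test_spike_reduced_mass_preserved(self, water_grid):
        b = flat_bolus(water_grid, 0.0)
        t = b.thickness.copy()
        i = water_grid.x.size // 2
        t[i, i] = 3.0
        b = dataclasses.replace(b, thickness=t)
        s = op_smooth(b, 2, 1)
        assert s.thickness[i, i] < 3.0
        assert s.thickness.sum() == pytest.approx(3.0, rel=0.005)

    def test_variance_monotone_under_repeated_smoothing(self, beam):
        grid, ptv = ib.wavy_slab_phantom()
        b = op_create(ptv, grid, beam)
        v = [b.thickness.var()]
        for _ in range(3):
            b = op_smooth(b, 2, 1)
            v.append(b.thickness.var())
        assert all(v[i + 1] < v[i] for i in range(3))

    def test_footprint_unchanged(self, water_grid, aperture):
        b = op_truncate(flat_bolus(water_grid), aperture)
        s = op_smooth(b, 2, 1)
        assert np.array_equal(s.footprint, b.footprint)


class TestSpecifiedShift:
    def test_uniform_reduction(self, water_grid):
        b = flat_bolus(water_grid, 1.0)
        assert np.allclose(op_specified_shift(b, -0.1).thickness, 0.9)

    def test_zero_delta_is_identity(self, water_grid):
        b = flat_bolus(water_grid, 1.0)
        assert np.array_equal(op_specified_shift(b, 0.0).thickness, b.thickness)

    def test_floored_at_zero(self, water_grid):
        b = flat_bolus(water_grid, 0.05)
        assert np.all(op_specified_shift(b, -0.1).thickness == 0.0)


class TestTruncate:
    def test_all_inside_footprint_is_identity(self, water_grid, aperture):
        t = np.zeros((water_grid.x.size, water_grid.y.size))
        inside = (np.abs(water_grid.x)[:, None] <= 3.0) & (np.abs(water_grid.y)[None, :] <= 3.0)
        t[:] = 1.0 * inside
        b = BolusSurface(x=water_grid.x, y=water_grid.y, thickness=t)
        assert np.allclose(op_truncate(b, aperture).thickness, t)

    def test_mass_strictly_decreases_when_outside_field(self, water_grid, aperture):
        b = flat_bolus(water_grid, 1.0)  # extends to the lattice edge
        tr = op_truncate(b, aperture)
        assert tr.mass_proxy < b.mass_proxy

    def test_in_field_dose_unchanged(self, water_grid, fan_for, beam, aperture):
        """Removing out-of-field bolus shifts in-field dose < 0.5%."""
        b = flat_bolus(water_grid, 2.0)
        d_full = ib.compute_dose(water_grid, fan_for, beam, bolus=b)
        d_trunc = ib.compute_dose(water_grid, fan_for, beam, bolus=op_truncate(b, aperture))
        infield = np.abs(water_grid.x) <= 4.5
        delta = np.abs(d_full.values - d_trunc.values)[np.ix_(infield, infield)]
        assert delta.max() < 0.5


class TestHeightExtension:
    def test_all_eligible_is_identity(self, water_grid):
        b = flat_bolus(water_grid, 1.0)
        el = np.ones(b.thickness.shape, dtype=bool)
        assert op_height_extension(b, el) is b

    def test_single_eligible_line_gives_constant_map(self, water_grid):
        b = flat_bolus(water_grid, 0.0)
        t = b.thickness.copy()
        t[10, 12] = 1.7
        b = dataclasses.replace(b, thickness=t)
        el = np.zeros(t.shape, dtype=bool)
        el[10, 12] = True
        out = op_height_extension(b, el)
        assert np.all(out.thickness == 1.7)

    def test_two_points_split_by_nearest_neighbor(self, water_grid):
        b = flat_bolus(water_grid, 0.0)
        t = b.thickness.copy()
        n = water_grid.x.size
        t[5, n // 2] = 1.0
        t[n - 6, n // 2] = 2.0
        b = dataclasses.replace(b, thickness=t)
        el = np.zeros(t.shape, dtype=bool)
        el[5, n // 2] = el[n - 6, n // 2] = True
        out = op_height_extension(b, el)
        assert out.thickness[7, n // 2] == 1.0
        assert out.thickness[n - 8, n // 2] == 2.0

    def test_no_eligible_rejected(self, water_grid):
        with pytest.raises(ValueError):
            op_height_extension(flat_bolus(water_grid), np.zeros(
                (water_grid.x.size, water_grid.y.size), dtype=bool))


class TestIsodoseShift:
    def _synthetic_dose(self, grid, ptv, offset=0.0):
        """Dose falling linearly through 90% exactly at z_distal + offset."""
        zd = distal_ptv_depth(ptv, grid)
        zd = np.where(np.isfinite(zd), zd, 103.0) + offset
        z = grid.z
        vals = 90.0 + 5.0 * (zd[:, :, None] - z[None, None, :])
        return ib.Dose3D(grid=grid, values=np.clip(vals, 0.0, None))

    def test_conformal_dose_is_fixed_point(self, beam):
        grid, ptv = ib.wavy_slab_phantom()
        b = flat_bolus(grid, 1.0)
        dose = self._synthetic_dose(grid, ptv)
        out, skipped = op_isodose_shift(b, dose, ptv)
        assert skipped == 0
        assert np.allclose(out.thickness, b.thickness, atol=1e-6)

    def test_residual_converted_to_thickness(self, beam):
        """z90 0.4 cm deep of the distal PTV -> thickness rises 0.4/density."""
        grid, ptv = ib.wavy_slab_phantom()
        b = flat_bolus(grid, 1.0)
        dose = self._synthetic_dose(grid, ptv, offset=0.4)
        out, _ = op_isodose_shift(b, dose, ptv)
        el = eroded_ptv_projection(ptv, grid, 0.5)
        assert np.allclose(out.thickness[el] - 1.0, 0.4 / b.density, atol=1e-6)

    def test_lines_without_crossing_left_unchanged(self, water_grid):
        grid = water_grid
        b = flat_bolus(grid, 1.0)
        ptv = np.zeros(grid.shape, dtype=bool)
        ptv[20:40, 20:40, 5:15] = True
        low = ib.Dose3D(grid=grid, values=np.full(grid.shape, 50.0))
        out, skipped = op_isodose_shift(b, low, ptv)
        assert skipped > 0
        assert np.array_equal(out.thickness, b.thickness)


class TestSequences:
    def test_empty_sequence_returns_nothing(self, beam, aperture):
        grid, ptv = ib.wavy_slab_phantom()
        res = run_sequence([], grid, ptv, beam, aperture)
        assert res.bolus is None and res.dose is None
        assert res.log == []

    def test_log_has_one_entry_per_operator(self, beam, aperture):
        grid, ptv = ib.wavy_slab_phantom()
        seq = bect_sequence()
        res = run_sequence(seq, grid, ptv, beam, aperture)
        assert len(res.log) == len(seq)
        assert [e["op"] for e in res.log] == [s[0] for s in seq]

    def test_unknown_operator_rejected(self, beam, aperture):
        grid, ptv = ib.wavy_slab_phantom()
        with pytest.raises(ValueError, match="unknown operator"):
            run_sequence([("polish", {})], grid, ptv, beam, aperture)

    def test_iterating_shift_improves_conformality(self, beam, aperture):
        """Create + 2x(IsodoseShift+Smooth) beats Create alone."""
        grid, ptv = ib.wavy_slab_phantom()
        create_only = [("create", {"percent": 90, "inner_margin": 0.7}),
                       ("smooth", {"exp_mult": 2, "radius_mult": 1})]
        res0 = run_sequence(create_only, grid, ptv, beam, aperture)
        res2 = run_sequence(bect_sequence(2, final_delta=None), grid, ptv, beam, aperture)

        def max_resid(res):
            z90, found = depth_of_90(res.dose)
            zd = distal_ptv_depth(ptv, grid)
            el = eroded_ptv_projection(ptv, grid, 0.5) & found
            return np.nanmax(np.abs((z90 - zd)[el]))

        assert max_resid(res2) < max_resid(res0)
        assert conformality(res2.dose, ptv) > conformality(res0.dose, ptv)
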