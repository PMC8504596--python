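import numpy as np
import pytest
from scipy.ndimage import shift as ndshift

import imbect as ib
from imbect.metrics import dvh, metric_d_span, normalize_match_v95
from imbect.planar import PlanarDose


def flat_field(value=100.0, half=5.0, pixel=0.1):
    x = np.arange(-half, half + pixel / 2, pixel)
    return PlanarDose(x=x, y=x.copy(), values=np.full((x.size, x.size), value), depth=2.0)


def gradient_field(half=5.0, pixel=0.1, slope=10.0):
    x = np.arange(-half, half + pixel / 2, pixel)
    vals = 60.0 + slope * np.broadcast_to(x[:, None], (x.size, x.size))
    return PlanarDose(x=x, y=x.copy(), values=vals.copy(), depth=2.0)


def shifted(p: PlanarDose, dx_cm: float) -> PlanarDose:
    vals = ndshift(p.values, (dx_cm / p.pixel, 0), order=1, mode="nearest")
    return PlanarDose(x=p.x, y=p.y, values=vals, depth=p.depth, ssd=p.ssd)


class TestDoseDifference:
    def test_identical_grids_zero(self):
        p = flat_field()
        assert np.all(ib.dose_difference(p, p) == 0.0)

    def test_uniform_offset(self):
        p = flat_field(100.0)
        m = flat_field(105.0)
        assert np.allclose(ib.dose_difference(p, m), 5.0)

    def test_resampled_linear_ramp_half_pixel_shift(self):
        """Bilinear resampling of a shifted ramp gives slope * shift."""
        calc = gradient_field(slope=10.0)
        half_pix = calc.pixel / 2.0
        m = PlanarDose(
            x=calc.x + half_pix, y=calc.y, values=calc.values.copy(), depth=2.0
        )
        diff = ib.dose_difference(calc, m)
        inner = diff[2:-2, 2:-2]
        assert np.allclose(inner, -10.0 * half_pix, atol=1e-6)


class TestDta:
    def test_identical_distributions_zero(self):
        p = gradient_field()
        assert np.all(ib.dta(p, p) <= 0.026)  # one fine pixel

    def test_uniform_gradient_shift_recovers_shift(self):
        calc = gradient_field(slope=10.0)
        meas = shifted(calc, 0.25)
        d = ib.dta(calc, meas)
        inner = d[10:-10, 10:-10]
        assert np.median(inner) == pytest.approx(0.25, abs=0.03)

    def test_flat_offset_caps(self):
        d = ib.dta(flat_field(100.0), flat_field(105.0), cap=1.0)
        assert np.all(d == 1.0)


class TestCompositePass:
    def test_self_compare_full_pass(self, beam, aperture):
        calc = ib.planar_dose(beam, aperture, None, depth=2.0)
        assert ib.composite_pass(calc, calc).pass_rate == 100.0

    def test_flat_offset_fails_everywhere(self):
        r = ib.composite_pass(flat_field(100.0), flat_field(105.0))
        assert r.pass_rate == 0.0

    def test_shifted_penumbra_passes_via_dta(self, beam, aperture):
        calc = ib.planar_dose(beam, aperture, None, depth=2.0)
        meas = shifted(calc, 0.25)
        r = ib.composite_pass(calc, meas, dose_tol=3.0, dist_tol=0.3)
        assert r.pass_rate == 100.0

    def test_pass_rate_monotone_in_tolerances(self, beam, aperture):
        calc = ib.planar_dose(beam, aperture, None, depth=2.0)
        meas = shifted(calc, 0.4)
        rates = [
            ib.composite_pass(calc, meas, dose_tol=dt, dist_tol=dd).pass_rate
            for dt, dd in [(1.0, 0.1), (3.0, 0.3), (5.0, 0.5)]
        ]
        assert rates[0] <= rates[1] <= rates[2]

    def test_threshold_mask_and_histogram_bookkeeping(self, beam, aperture):
        calc = ib.planar_dose(beam, aperture, None, depth=2.0)
        r = ib.composite_pass(calc, calc, threshold=10.0)
        assert np.array_equal(r.mask, calc.values >= 0.1 * calc.values.max())
        assert r.histogram_counts.sum() == r.mask.sum()


class TestGamma:
    def test_identical_gamma_near_zero(self):
        p = gradient_field()
        g = ib.gamma_index(p, p)
        assert np.nanmax(g) < 0.2

    def test_small_shift_passes_gamma(self):
        calc = gradient_field()
        g = ib.gamma_index(calc, shifted(calc, 0.2))
        inner = g[10:-10, 10:-10]
        assert np.nanmax(inner) <= 1.0


class TestDvhMetrics:
    def test_uniform_dose_zero_span(self):
        vals = np.full((10, 10, 10), 100.0)
        mask = np.ones(vals.shape, dtype=bool)
        h = dvh(vals, mask)
        assert metric_d_span(h) == pytest.approx(0.0, abs=0.3)

    def test_linear_dose_closed_form(self):
        """Uniformly distributed dose 90..110: D10=108, D90=92, span 16."""
        vals = np.linspace(90.0, 110.0, 200001).reshape(1, 1, -1)
        mask = np.ones(vals.shape, dtype=bool)
        h = dvh(vals, mask, bins=4000)
        assert h.dose_at_volume(10.0) == pytest.approx(108.0, abs=0.1)
        assert h.dose_at_volume(90.0) == pytest.approx(92.0, abs=0.1)
        assert metric_d_span(h) == pytest.approx(16.0, abs=0.2)

    def test_v95_of_uniform_96(self):
        vals = np.full((5, 5, 5), 96.0)
        h = dvh(vals, np.ones(vals.shape, dtype=bool))
        assert h.volume_at_dose(95.0) == pytest.approx(100.0)

    def test_dvh_invariants(self):
        rng = np.random.default_rng(7)
        vals = rng.uniform(0, 110, size=(20, 20, 20))
        h = dvh(vals, np.ones(vals.shape, dtype=bool))
        assert h.volume_pct[0] == 100.0
        assert np.all(np.diff(h.volume_pct) <= 1e-9)


class TestV95Matching:
    def _doses(self):
        rng = np.random.default_rng(3)
        a = rng.normal(100.0, 4.0, size=(20, 20, 20)).clip(min=0)
        return a

    def test_identity_factor_one(self):
        a = self._doses()
        ptv = np.ones(a.shape, dtype=bool)
        _, f = normalize_match_v95(a, a, ptv)
        assert f == pytest.approx(1.0, abs=0.01)

    def test_half_dose_needs_factor_two(self):
        a = self._doses()
        ptv = np.ones(a.shape, dtype=bool)
        scaled, f = normalize_match_v95(a, 0.5 * a, ptv)
        assert f == pytest.approx(2.0, abs=0.02)
        v95a = 100.0 * np.count_nonzero(a >= 95) / a.size
        v95b = 100.0 * np.count_nonzero(scaled >= 95) / a.size
        assert v95b == pytest.approx(v95a, abs=0.5)

    def test_monotone_in_target(self):
        a = self._doses()
        ptv = np.ones(a.shape, dtype=bool)
        _, f_low = normalize_match_v95(0.95 * a, 0.5 * a, ptv)
        _, f_high = normalize_match_v95(1.05 * a, 0.5 * a, ptv)
        assert f_high >= f_low
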