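import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate
from scipy.stats import kstest, norm
from scipy.stats import skewnorm as sp_skewnorm

from snroc.skewnorm import (
    SKEWNESS_SUP,
    SkewnessInfeasibleWarning,
    SNMoments,
    SNParams,
    alpha_from_delta,
    delta_from_alpha,
    sn_cdf,
    sn_from_moments,
    sn_moments,
    sn_pdf,
    sn_quantile,
    sn_rvs,
    skewness_from_delta,
)


class TestPdf:
    @pytest.mark.parametrize("alpha", [-5.0, 0.0, 1.0, 6.0])
    def test_density_at_location_is_phi0(self, alpha):
        # Phi(0) = 1/2 cancels the factor 2 regardless of shape
        assert sn_pdf(0.0, SNParams(0.0, 1.0, alpha)) == pytest.approx(
            norm.pdf(0.0), abs=1e-12
        )

    def test_zero_shape_reduces_to_normal(self):
        x = np.linspace(-6, 6, 1000)
        p = SNParams(0.3, 1.7, 0.0)
        assert np.max(np.abs(sn_pdf(x, p) - norm.pdf(x, 0.3, 1.7))) < 1e-12
        assert np.max(np.abs(sn_cdf(x, p) - norm.cdf(x, 0.3, 1.7))) < 1e-12

    def test_integrates_to_one(self):
        val, _ = integrate.quad(lambda x: sn_pdf(x, SNParams(3.0, 1.0, 6.0)), -10, 15)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            sn_pdf(np.nan, SNParams(0, 1, 0))
        with pytest.raises(ValueError):
            SNParams(0.0, -1.0, 0.0)


class TestCdf:
    def test_median_at_location_when_symmetric(self):
        assert sn_cdf(2.0, SNParams(2.0, 3.0, 0.0)) == pytest.approx(0.5, abs=1e-12)

    def test_limits(self):
        p = SNParams(0.0, 1.0, 4.0)
        assert sn_cdf(-50.0, p) == pytest.approx(0.0, abs=1e-12)
        assert sn_cdf(50.0, p) == pytest.approx(1.0, abs=1e-12)

    def test_matches_quadrature_of_density(self):
        p = SNParams(0.0, 1.0, 1.0)
        want, _ = integrate.quad(lambda x: sn_pdf(x, p), -np.inf, 0.0)
        assert sn_cdf(0.0, p) == pytest.approx(want, abs=1e-8)

    def test_quantile_round_trip(self):
        p = SNParams(1.0, 2.0, -3.0)
        q = np.arange(0.01, 1.0, 0.01)
        assert np.max(np.abs(sn_cdf(sn_quantile(q, p), p) - q)) < 1e-8


class TestMoments:
    def test_normal_case(self):
        m = sn_moments(SNParams(5.0, 2.0, 0.0))
        assert (m.mean, m.variance, m.skewness) == (5.0, 4.0, 0.0)

    def test_closed_form_matches_scipy_stats(self):
        for alpha in (-4.0, math.sqrt(6), 6.0):
            m = sn_moments(SNParams(0.0, 1.0, alpha))
            mean, var, skew = sp_skewnorm.stats(alpha, moments="mvs")
            assert m.mean == pytest.approx(float(mean), abs=1e-12)
            assert m.variance == pytest.approx(float(var), abs=1e-12)
            assert m.skewness == pytest.approx(float(skew), abs=1e-10)

    def test_root6_shape_skewness(self):
        # delta = sqrt(6/7); closed form evaluates to about 0.565
        m = sn_moments(SNParams(0.0, 1.0, math.sqrt(6)))
        assert m.skewness == pytest.approx(0.56495, abs=5e-5)

    def test_skewness_supremum(self):
        assert skewness_from_delta(1 - 1e-9) == pytest.approx(SKEWNESS_SUP, abs=1e-6)
        assert SKEWNESS_SUP == pytest.approx(0.99527, abs=1e-5)


class TestFromMoments:
    def test_normal_moments_give_normal(self):
        p, clamped = sn_from_moments(SNMoments(3.0, 1.0, 0.0))
        assert not clamped
        assert (p.xi, p.omega, p.alpha) == (3.0, 1.0, 0.0)

    @pytest.mark.parametrize("alpha", [-10.0, -2.0, -0.5, 0.0, 0.5, math.sqrt(6), 6.0, 10.0])
    @pytest.mark.parametrize("omega", [0.5, 1.0, 2.0])
    def test_round_trip_on_parameter_grid(self, alpha, omega):
        p0 = SNParams(xi=-0.7, omega=omega, alpha=alpha)
        m = sn_moments(p0)
        p1, clamped = sn_from_moments(m)
        assert not clamped
        assert p1.xi == pytest.approx(p0.xi, abs=1e-6)
        assert p1.omega == pytest.approx(p0.omega, abs=1e-6)
        assert p1.alpha == pytest.approx(p0.alpha, abs=1e-4 * max(1, abs(alpha)))

    def test_near_boundary_skewness_round_trip(self):
        m0 = SNMoments(0.0, 1.0, 0.99)
        p, clamped = sn_from_moments(m0)
        assert not clamped and abs(p.alpha) > 20
        m1 = sn_moments(p)
        assert m1.skewness == pytest.approx(0.99, abs=1e-6)

    def test_root_finder_agrees_with_dense_grid(self):
        # brute-force oracle: nearest delta on a dense grid of the skewness map
        target = 0.8
        grid = np.linspace(0, 1 - 1e-9, 400001)
        vals = np.array([skewness_from_delta(d) for d in grid])
        d_grid = grid[np.argmin(np.abs(vals - target))]
        p, _ = sn_from_moments(SNMoments(0.0, 1.0, target))
        assert delta_from_alpha(p.alpha) == pytest.approx(d_grid, abs=1e-5)

    def test_infeasible_skewness_clamps_with_warning(self):
        with pytest.warns(SkewnessInfeasibleWarning):
            p, clamped = sn_from_moments(SNMoments(0.0, 1.0, 1.2))
        assert clamped
        assert delta_from_alpha(p.alpha) == pytest.approx(1 - 1e-6, abs=1e-9)
        with pytest.raises(ValueError):
            sn_from_moments(SNMoments(0.0, 1.0, 1.2), clamp=False)

    @given(
        mean=st.floats(-5, 5),
        var=st.floats(0.1, 9.0),
        skew=st.floats(-0.99, 0.99),
    )
    @settings(max_examples=60, deadline=None)
    def test_moment_inversion_property(self, mean, var, skew):
        p, clamped = sn_from_moments(SNMoments(mean, var, skew))
        assert not clamped
        m = sn_moments(p)
        assert m.mean == pytest.approx(mean, abs=1e-9)
        assert m.variance == pytest.approx(var, abs=1e-9)
        assert m.skewness == pytest.approx(skew, abs=1e-9)


class TestSampling:
    def test_seed_determinism(self):
        p = SNParams(0.0, 1.0, 2.0)
        assert np.array_equal(sn_rvs(p, 1000, 42), sn_rvs(p, 1000, 42))

    def test_normal_case_mean(self):
        x = sn_rvs(SNParams(0.0, 1.0, 0.0), 10**6, 3)
        assert abs(x.mean()) < 4e-3

    def test_sample_skewness_matches_closed_form(self):
        p = SNParams(0.0, 1.0, math.sqrt(6))
        x = sn_rvs(p, 10**6, 11)
        z = (x - x.mean()) / x.std()
        assert np.mean(z**3) == pytest.approx(sn_moments(p).skewness, abs=0.01)

    def test_distribution_matches_cdf(self):
        p = SNParams(1.0, 2.0, -4.0)
        x = sn_rvs(p, 10**5, 5)
        stat = kstest(x, lambda v: sn_cdf(v, p))
        assert stat.pvalue > 1e-4


def test_delta_alpha_maps_are_inverse():
    for a in (-7.0, -1.0, 0.0, 0.3, 12.0):
        assert alpha_from_delta(delta_from_alpha(a)) == pytest.approx(a, rel=1e-12)
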