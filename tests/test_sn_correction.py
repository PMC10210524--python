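import math

import numpy as np
import pytest

from snroc.cfa import attenuate_auc, correct_auc
from snroc.measurement_model import IdentificationError
from snroc.skewnorm import SNParams, sn_moments, sn_rvs
from snroc.sn_correction import (
    SNGroupFit,
    fit_group_sn,
    sn_auc,
    sn_auc_quadrature,
    sn_roc,
    sn_sensitivity,
    sn_specificity,
    sn_wm_estimate,
)
from snroc.simulation import Scenario, _sn_group_params

LN32 = math.log(3.2)


def _standardized_sn(shape: float, mean: float = 3.0):
    """SN params with the given shape, unit variance and the given mean."""
    base = sn_moments(SNParams(0.0, 1.0, shape))
    omega = 1.0 / math.sqrt(base.variance)
    return SNParams(xi=mean - base.mean * omega, omega=omega, alpha=shape)


class TestFitGroupSN:
    def test_noiseless_parameter_recovery(self):
        p = SNParams(0.0, 1.0, math.sqrt(6))
        x = sn_rvs(p, 10**6, 21)
        fit = fit_group_sn(x, 0.0)
        assert fit.params.xi == pytest.approx(p.xi, abs=0.01)
        assert fit.params.omega == pytest.approx(p.omega, abs=0.01)
        assert fit.params.alpha == pytest.approx(p.alpha, abs=0.15)
        assert not fit.clamped

    def test_error_corrected_recovery(self):
        p = _standardized_sn(math.sqrt(6))
        rng = np.random.default_rng(22)
        x = sn_rvs(p, 10**6, rng)
        w = x + rng.normal(0.0, 1.0, x.size)
        fit = fit_group_sn(w, 1.0)
        assert fit.params.alpha == pytest.approx(p.alpha, abs=0.2)
        # ignoring the error biases the shape toward symmetry
        naive = fit_group_sn(w, 0.0)
        assert abs(naive.params.alpha) < abs(fit.params.alpha)

    def test_normal_data_gives_near_normal_fit(self):
        # the delta root scales as the cube root of the sample skewness, so
        # alpha itself converges slowly at the normal boundary; the fitted
        # distribution's skewness is the statistically stable quantity
        rng = np.random.default_rng(23)
        x = rng.normal(3.0, 1.0, 10**6)
        fit = fit_group_sn(x, 0.0)
        assert abs(sn_moments(fit.params).skewness) < 0.01
        assert abs(fit.params.alpha) < 0.6
        assert sn_moments(fit.params).mean == pytest.approx(3.0, abs=0.01)
        assert sn_moments(fit.params).variance == pytest.approx(1.0, abs=0.01)

    def test_variance_swamped_by_error_rejected(self):
        rng = np.random.default_rng(24)
        w = rng.normal(0.0, 1.0, 100)
        with pytest.raises(IdentificationError):
            fit_group_sn(w, 5.0)

    def test_fitted_variance_matches_corrected_observed(self):
        rng = np.random.default_rng(25)
        w = rng.normal(3.0, 1.5, 5000)
        s2_w = np.mean((w - w.mean()) ** 2)
        fit = fit_group_sn(w, 0.5)
        assert sn_moments(fit.params).variance == pytest.approx(s2_w - 0.5, rel=1e-9)


class TestSeSp:
    def test_extreme_cutoff_limits(self):
        fit = SNGroupFit(SNParams(3.0, 1.0, 2.0), 0.0, 100)
        assert sn_sensitivity(fit, -50.0) == pytest.approx(1.0)
        assert sn_specificity(fit, -50.0) == pytest.approx(0.0)

    def test_symmetric_binormal_midpoint(self):
        from scipy.stats import norm

        f0 = SNGroupFit(SNParams(3.0, 1.0, 0.0), 0.0, 100)
        f1 = SNGroupFit(SNParams(3.0 + LN32, 1.0, 0.0), 0.0, 100)
        c = 3.0 + LN32 / 2.0
        want = norm.cdf(LN32 / 2.0)
        assert sn_sensitivity(f1, c) == pytest.approx(want, abs=1e-12)
        assert sn_specificity(f0, c) == pytest.approx(want, abs=1e-12)
        assert want == pytest.approx(0.7196, abs=5e-4)


class TestRocAuc:
    def test_identical_groups_give_half(self):
        fit = SNGroupFit(SNParams(0.0, 1.0, 3.0), 0.0, 100)
        assert sn_auc(sn_roc(fit, fit)) == pytest.approx(0.5, abs=1e-4)

    def test_binormal_limit(self):
        f0 = SNGroupFit(SNParams(3.0, 1.0, 0.0), 0.0, 100)
        f1 = SNGroupFit(SNParams(3.0 + LN32, 1.0, 0.0), 0.0, 100)
        assert sn_auc(sn_roc(f0, f1)) == pytest.approx(0.7946, abs=2e-4)

    def test_skewed_scenario_auc(self):
        p0, p1 = _sn_group_params(6.0)
        f0, f1 = SNGroupFit(p0, 0.0, 100), SNGroupFit(p1, 0.0, 100)
        auc = sn_auc(sn_roc(f0, f1))
        assert auc == pytest.approx(0.806, abs=2e-3)

    def test_trapezoid_agrees_with_quadrature(self):
        f0 = SNGroupFit(SNParams(3.0, 1.1, 4.0), 0.0, 100)
        f1 = SNGroupFit(SNParams(3.6, 0.9, -2.0), 0.0, 100)
        assert sn_auc(sn_roc(f0, f1)) == pytest.approx(
            sn_auc_quadrature(f0, f1), abs=2e-4
        )

    def test_grid_convergence_by_doubling(self):
        p0, p1 = _sn_group_params(6.0)
        f0, f1 = SNGroupFit(p0, 0.0, 100), SNGroupFit(p1, 0.0, 100)
        a1 = sn_auc(sn_roc(f0, f1, grid_size=2001))
        a2 = sn_auc(sn_roc(f0, f1, grid_size=4001))
        assert abs(a1 - a2) < 5e-5

    def test_roc_monotonicity(self):
        f0 = SNGroupFit(SNParams(3.0, 1.0, 5.0), 0.0, 100)
        f1 = SNGroupFit(SNParams(4.0, 1.3, -1.0), 0.0, 100)
        roc = sn_roc(f0, f1)
        assert np.all(np.diff(roc.se) <= 1e-12)
        assert np.all(np.diff(roc.sp) >= -1e-12)

    def test_degenerate_grid_rejected(self):
        fit = SNGroupFit(SNParams(0.0, 1.0, 0.0), 0.0, 100)
        with pytest.raises(ValueError):
            sn_roc(fit, fit, grid_size=10)


class TestPipeline:
    def test_noiseless_inputs_equal_direct_fit(self):
        p = _standardized_sn(math.sqrt(6))
        rng = np.random.default_rng(31)
        n = 2000
        y = np.repeat([0.0, 1.0], n // 2)
        x = sn_rvs(p, n, rng) + LN32 * y
        est = sn_wm_estimate(y, x, x, cutoff=3.0 + LN32 / 2.0)
        f0 = fit_group_sn(x[y == 0], 0.0)
        f1 = fit_group_sn(x[y == 1], 0.0)
        want = sn_auc(sn_roc(f0, f1))
        assert est.auc == pytest.approx(want, abs=1e-9)

    def test_normal_scenario_small_bias(self):
        # error-corrected AUC over replicates stays near the population truth
        from scipy.stats import norm

        rng = np.random.default_rng(32)
        reps, n = 100, 300
        truth = norm.cdf(LN32 / math.sqrt(2.0))
        cutoff = 3.0 + LN32 / 2.0
        vals = []
        for _ in range(reps):
            y = np.repeat([0.0, 1.0], n // 2)
            x = rng.normal(3.0 + LN32 * y, 1.0)
            w = x + rng.normal(0.0, 1.0, n)
            m = x + rng.normal(0.0, 1.0, n)
            vals.append(sn_wm_estimate(y, w, m, cutoff=cutoff).auc)
        vals = np.asarray(vals)
        mc_se = vals.std(ddof=1) / math.sqrt(reps)
        assert abs(vals.mean() - truth) < max(2 * mc_se, 0.01)

    def test_normal_limit_ties_to_cfa(self):
        # with symmetric groups the SN route reproduces the probit
        # de-attenuation applied to the attenuated binormal AUC
        f0 = SNGroupFit(SNParams(3.0, 1.0, 0.0), 1.0, 150)
        f1 = SNGroupFit(SNParams(3.0 + LN32, 1.0, 0.0), 1.0, 150)
        sn_val = sn_auc(sn_roc(f0, f1))
        cfa_val = correct_auc(attenuate_auc(0.7946, 1.0), 1.0)
        assert sn_val == pytest.approx(cfa_val, abs=1e-3)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            sn_wm_estimate(np.zeros(10), np.arange(10.0), np.arange(10.0))
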