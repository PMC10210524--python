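"""Skew-normal biomarker correction estimator.

Rather than de-attenuating an observed accuracy measure, this estimator
reconstructs the latent biomarker distribution in each disease group as a
skew-normal and reads sensitivity, specificity, the ROC curve and the
AUC off the fitted distributions.  The key observation is that with an
additive symmetric error U, the observed series W = X + U shares the
mean and the third central moment of X, and its variance exceeds that of
X by exactly the error variance.  Subtracting a consistently estimated
``sigma_u^2`` from the observed variance therefore recovers the first
three moments of X, and those determine a unique skew-normal through the
monotone delta-parameterized moment map.

The group fit solves the estimating equations

    mean:      xi + omega*delta*sqrt(2/pi)            = Wbar
    variance:  omega^2*(1 - 2*delta^2/pi)             = S_W^2 - sigma_u^2
    skewness:  m3 / (S_W^2 - sigma_u^2)^{3/2}         = SN skewness(delta)

with divisor-n sample central moments, via the closed-form inversion in
:func:`snroc.skewnorm.sn_from_moments`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .measurement_model import (
    Calibration,
    IdentificationError,
    combine,
    linear_calibration,
    moments_two_unbiased,
    optimal_weight,
    rescale_m,
)
from .roc_empirical import AccuracyEstimate
from .skewnorm import SNMoments, SNParams, sn_cdf, sn_from_moments, sn_pdf, sn_quantile

__all__ = [
    "SNGroupFit",
    "ROCCurve",
    "fit_group_sn",
    "sn_sensitivity",
    "sn_specificity",
    "sn_roc",
    "sn_auc",
    "sn_auc_quadrature",
    "sn_wm_estimate",
]


@dataclass(frozen=True)
class SNGroupFit:
    """Error-corrected skew-normal fit for one disease group."""

    params: SNParams
    sigma2_u: float
    n: int
    clamped: bool = False


@dataclass(frozen=True)
class ROCCurve:
    """Sensitivity/specificity along an ordered cutoff grid."""

    cutoffs: np.ndarray
    se: np.ndarray
    sp: np.ndarray


def fit_group_sn(W_group, sigma2_u: float, *, clamp: bool = True) -> SNGroupFit:
    """Fit an error-corrected skew-normal to one group's observed series.

    ``sigma2_u`` is the (estimated) additive error variance of the series;
    0 fits the observed data directly.  Requires the observed variance to
    exceed ``sigma2_u`` — otherwise all observed variation would be noise
    and the latent distribution is not identified.  An infeasible sample
    skewness (|skew| at or beyond the SN supremum 0.99528) yields the
    clamped boundary fit, flagged on the result.
    """
    W = np.asarray(W_group, dtype=float)
    if W.ndim != 1 or W.size < 3:
        raise ValueError("need a 1-d sample with n >= 3 (n >= 8 recommended)")
    if sigma2_u < 0:
        raise ValueError("sigma2_u must be nonnegative")
    wbar = float(W.mean())
    s2_w = float(np.mean((W - wbar) ** 2))
    s2_x = s2_w - sigma2_u
    if s2_x <= 0:
        raise IdentificationError(
            f"observed variance {s2_w:.4g} does not exceed the error variance "
            f"{sigma2_u:.4g}: latent biomarker variance not identified"
        )
    m3 = float(np.mean((W - wbar) ** 3))
    skew = m3 / s2_x**1.5
    params, clamped = sn_from_moments(
        SNMoments(mean=wbar, variance=s2_x, skewness=skew), clamp=clamp
    )
    return SNGroupFit(params=params, sigma2_u=sigma2_u, n=W.size, clamped=clamped)


def sn_sensitivity(fit1: SNGroupFit, c: float) -> float:
    """P(X >= c | case) under the fitted case distribution."""
    return float(1.0 - sn_cdf(c, fit1.params))


def sn_specificity(fit0: SNGroupFit, c: float) -> float:
    """P(X <= c | control) under the fitted control distribution."""
    return float(sn_cdf(c, fit0.params))


def sn_roc(fit0: SNGroupFit, fit1: SNGroupFit, grid_size: int = 2001) -> ROCCurve:
    """ROC curve of the two fitted distributions over a quantile-spanning grid.

    The cutoff grid covers the union of both groups' 1e-6 … 1-1e-6
    quantile ranges.
    """
    if grid_size < 100:
        raise ValueError("grid_size must be >= 100")
    q = (1e-6, 1.0 - 1e-6)
    lo = min(float(sn_quantile(q[0], fit0.params)), float(sn_quantile(q[0], fit1.params)))
    hi = max(float(sn_quantile(q[1], fit0.params)), float(sn_quantile(q[1], fit1.params)))
    if not hi > lo:
        raise ValueError("degenerate cutoff grid")
    cutoffs = np.linspace(lo, hi, grid_size)
    se = 1.0 - sn_cdf(cutoffs, fit1.params)
    sp = sn_cdf(cutoffs, fit0.params)
    return ROCCurve(cutoffs=cutoffs, se=se, sp=sp)


def sn_auc(roc: ROCCurve) -> float:
    """AUC by trapezoidal integration of Se against 1 - Sp.

    Endpoints (0,0) and (1,1) in (1-Sp, Se) space are appended so the
    integral covers the whole unit interval.
    """
    fpr = 1.0 - np.asarray(roc.sp, dtype=float)
    tpr = np.asarray(roc.se, dtype=float)
    order = np.argsort(fpr)
    fpr, tpr = fpr[order], tpr[order]
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    return float(np.trapezoid(tpr, fpr))


def sn_auc_quadrature(fit0: SNGroupFit, fit1: SNGroupFit) -> float:
    """AUC = P(X1 > X0) by direct quadrature of f1(x) * F0(x).

    Independent of the ROC/trapezoid route; used as an internal
    cross-check and for population truth values.
    """
    lo = min(float(sn_quantile(1e-9, p)) for p in (fit0.params, fit1.params))
    hi = max(float(sn_quantile(1.0 - 1e-9, p)) for p in (fit0.params, fit1.params))
    val, _ = integrate.quad(
        lambda x: sn_pdf(x, fit1.params) * sn_cdf(x, fit0.params), lo, hi, limit=400
    )
    return float(val)


def sn_wm_estimate(
    Y,
    W,
    M,
    model: str = "unbiased_pair",
    cutoff: float | None = None,
    *,
    use_composite: bool = True,
    grid_size: int = 2001,
) -> AccuracyEstimate:
    """Full skew-normal correction pipeline from raw two-assay data.

    Steps: (i) identify error variances per disease group (``model`` in
    {"unbiased_pair", "linear_m"}; the linear model first calibrates M
    against W through the disease indicator and pools error variances
    across groups, as its identification requires); (ii) form the
    minimum-variance composite gamma*W + (1-gamma)*M*; (iii) fit an
    error-corrected skew-normal per group; (iv) evaluate Se/Sp at
    ``cutoff`` and the AUC from the fitted ROC curve.

    With ``use_composite=False`` only the W series feeds the fit (its own
    error variance is still identified from the pair).
    """
    Y = np.asarray(Y, dtype=float)
    W = np.asarray(W, dtype=float)
    M = np.asarray(M, dtype=float)
    mask0, mask1 = Y == 0, Y == 1
    if not (np.any(mask0) and np.any(mask1)):
        raise ValueError("both disease groups must be nonempty")

    if model == "linear_m":
        cal = linear_calibration(Y, W, M)
        M_star = rescale_m(M, cal)
    elif model == "unbiased_pair":
        cal = Calibration(alpha0=0.0, alpha1=1.0)
        M_star = M
    else:
        raise ValueError(f"unknown model {model!r}")

    mom = {g: moments_two_unbiased(W[m], M_star[m]) for g, m in ((0, mask0), (1, mask1))}
    if model == "linear_m":
        # identification of the linear model requires equal error variances
        # across groups; pool them, keep sigma_x^2 per group
        n0, n1 = mom[0].n, mom[1].n
        su = (n0 * mom[0].sigma2_u + n1 * mom[1].sigma2_u) / (n0 + n1)
        sv = (n0 * mom[0].sigma2_v + n1 * mom[1].sigma2_v) / (n0 + n1)
        su_g = {0: su, 1: su}
        sv_g = {0: sv, 1: sv}
        gamma = optimal_weight(su, sv)
    else:
        su_g = {g: mom[g].sigma2_u for g in (0, 1)}
        sv_g = {g: mom[g].sigma2_v for g in (0, 1)}
        n0, n1 = mom[0].n, mom[1].n
        su_pool = (n0 * su_g[0] + n1 * su_g[1]) / (n0 + n1)
        sv_pool = (n0 * sv_g[0] + n1 * sv_g[1]) / (n0 + n1)
        gamma = optimal_weight(su_pool, sv_pool)

    fits = {}
    for g, mask in ((0, mask0), (1, mask1)):
        if use_composite:
            series = combine(W[mask], M_star[mask], gamma)
            err_var = gamma**2 * su_g[g] + (1.0 - gamma) ** 2 * sv_g[g]
        else:
            series = W[mask]
            err_var = su_g[g]
        fits[g] = fit_group_sn(series, err_var)

    roc = sn_roc(fits[0], fits[1], grid_size=grid_size)
    auc = min(max(sn_auc(roc), 0.0), 1.0)
    if cutoff is None:
        # default: midpoint ROC operating point closest to the (0,1) corner
        dist = (1.0 - roc.se) ** 2 + (1.0 - roc.sp) ** 2
        cutoff = float(roc.cutoffs[int(np.argmin(dist))])
    return AccuracyEstimate(
        auc=auc,
        sensitivity=sn_sensitivity(fits[1], cutoff),
        specificity=sn_specificity(fits[0], cutoff),
        cutoff=float(cutoff),
    )
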