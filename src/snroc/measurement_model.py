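"""Identification of measurement-error structure from two assay measures.

The measurement model is

    W = X + U,            E(U | X) = 0
    M = alpha0 + alpha1*X + V,   E(V | X) = 0

with X, U, V mutually independent.  When both measures are unbiased
(alpha0, alpha1) = (0, 1), the first two moments of (W, M) identify the
true-biomarker variance through the cross-moment E(WM) = sigma_x^2 +
mu_x^2, and hence the error variances sigma_u^2 = var(W) - sigma_x^2 and
sigma_v^2 = var(M) - sigma_x^2.  A biased linear M is first calibrated
using the disease indicator: alpha1 = cov(Y, M)/cov(Y, W), then rescaled
to the X scale.  The minimum-variance linear combination of the two
unbiased measures uses weight gamma = sigma_v^2/(sigma_u^2+sigma_v^2).

All variances and covariances use the population-style divisor ``n``,
matching the plug-in moment displays; the O(1/n) difference from the
n-1 convention is immaterial at the sample sizes involved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GroupMoments",
    "Calibration",
    "IdentificationError",
    "moments_two_unbiased",
    "replicate_variance_components",
    "linear_calibration",
    "rescale_m",
    "optimal_weight",
    "combine",
]


class IdentificationError(ValueError):
    """The requested variance components are not identified by the data."""


@dataclass(frozen=True)
class GroupMoments:
    """Moment estimates for one disease group.

    ``sigma2_u`` is the error variance of W, ``sigma2_v`` that of M (or of
    the rescaled M* when a calibration was applied).  ``third_central`` is
    the third central moment of W, which equals that of X under symmetric
    errors.
    """

    mu_x: float
    sigma2_x: float
    sigma2_u: float
    sigma2_v: float
    third_central: float
    n: int

    def __post_init__(self) -> None:
        if self.sigma2_x <= 0:
            raise IdentificationError(
                f"nonpositive true-biomarker variance estimate ({self.sigma2_x:.4g})"
            )
        if self.sigma2_u < 0 or self.sigma2_v < 0:
            raise ValueError("error variances must be nonnegative")


@dataclass(frozen=True)
class Calibration:
    """Linear calibration of assay M and the optimal combination weight."""

    alpha0: float
    alpha1: float
    gamma: float = 0.5

    def __post_init__(self) -> None:
        if self.alpha1 == 0:
            raise ValueError("alpha1 must be nonzero")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")


def _var_n(x: np.ndarray) -> float:
    return float(np.mean((x - x.mean()) ** 2))


def _clamp_nonneg(value: float, name: str) -> float:
    if value < 0:
        warnings.warn(
            f"negative {name} estimate ({value:.4g}) clamped to 0 "
            "(no detectable error)",
            UserWarning,
            stacklevel=3,
        )
        return 0.0
    return value


def moments_two_unbiased(W, M) -> GroupMoments:
    """Moment identification from a pair of unbiased noisy measures.

    mu_x    = mean of (W+M)/2
    sigma_x^2 = mean(W*M) - mu_x^2        (cross-moment)
    sigma_u^2 = var(W) - sigma_x^2
    sigma_v^2 = var(M) - sigma_x^2

    Negative error-variance estimates are clamped to 0 with a warning;
    a nonpositive sigma_x^2 estimate is fatal (not identified).
    """
    W = np.asarray(W, dtype=float)
    M = np.asarray(M, dtype=float)
    if W.shape != M.shape or W.ndim != 1:
        raise ValueError("W and M must be equal-length 1-d samples")
    n = W.size
    if n < 3:
        raise ValueError(f"need at least 3 paired observations, got {n}")
    mu_x = float(np.mean((W + M) / 2.0))
    sigma2_x = float(np.mean(W * M)) - mu_x**2
    if sigma2_x <= 0:
        raise IdentificationError(
            f"cross-moment variance estimate nonpositive ({sigma2_x:.4g})"
        )
    sigma2_u = _clamp_nonneg(_var_n(W) - sigma2_x, "sigma_u^2")
    sigma2_v = _clamp_nonneg(_var_n(M) - sigma2_x, "sigma_v^2")
    third = float(np.mean((W - mu_x) ** 3))
    return GroupMoments(mu_x, sigma2_x, sigma2_u, sigma2_v, third, n)


def replicate_variance_components(W, M) -> GroupMoments:
    """Within/between variance decomposition for true replicates.

    Assumes a common error variance sigma_u = sigma_v:
    sigma_u^2 = mean((W-M)^2)/2 (within-pair), and
    sigma_x^2 = var((W+M)/2) - sigma_u^2/2 (between minus the error share
    of the pair mean).
    """
    W = np.asarray(W, dtype=float)
    M = np.asarray(M, dtype=float)
    if W.shape != M.shape or W.ndim != 1:
        raise ValueError("W and M must be equal-length 1-d samples")
    if W.size < 3:
        raise ValueError("need at least 3 paired observations")
    sigma2_u = float(np.mean((W - M) ** 2) / 2.0)
    pair_mean = (W + M) / 2.0
    sigma2_x = _var_n(pair_mean) - sigma2_u / 2.0
    if sigma2_x <= 0:
        raise IdentificationError(
            f"between-pair variance estimate nonpositive ({sigma2_x:.4g})"
        )
    mu_x = float(pair_mean.mean())
    third = float(np.mean((W - W.mean()) ** 3))
    return GroupMoments(mu_x, sigma2_x, sigma2_u, sigma2_u, third, W.size)


def linear_calibration(Y, W, M) -> Calibration:
    """Identify (alpha0, alpha1) for a biased linear assay M.

    alpha1 = cov(Y, M)/cov(Y, W) and alpha0 = mean(M - alpha1*W).  Valid
    under equal error variances across disease groups — the caller asserts
    that assumption.  Divisor-n covariances.
    """
    Y = np.asarray(Y, dtype=float)
    W = np.asarray(W, dtype=float)
    M = np.asarray(M, dtype=float)
    if not (Y.shape == W.shape == M.shape):
        raise ValueError("Y, W, M must have equal length")
    if not (np.any(Y == 0) and np.any(Y == 1)):
        raise IdentificationError("both disease groups must be nonempty")
    cov_yw = float(np.mean((Y - Y.mean()) * (W - W.mean())))
    cov_ym = float(np.mean((Y - Y.mean()) * (M - M.mean())))
    if abs(cov_yw) <= 1e-10 * float(np.std(W)):
        raise IdentificationError("cov(Y, W) is numerically zero: W carries no signal for Y")
    alpha1 = cov_ym / cov_yw
    if alpha1 == 0:
        raise IdentificationError("estimated alpha1 is zero: M carries no signal for Y")
    alpha0 = float(np.mean(M - alpha1 * W))
    return Calibration(alpha0=alpha0, alpha1=alpha1)


def rescale_m(M, c: Calibration) -> np.ndarray:
    """Rescale a biased linear measure onto the X scale: M* = (M - alpha0)/alpha1.

    M* is unbiased for X with error variance sigma_v^2 / alpha1^2.
    """
    M = np.asarray(M, dtype=float)
    return (M - c.alpha0) / c.alpha1


def optimal_weight(sigma2_u: float, sigma2_v: float) -> float:
    """Minimum-variance combination weight gamma = sigma_v^2/(sigma_u^2+sigma_v^2).

    The composite gamma*W + (1-gamma)*M* has error variance
    sigma_u^2*sigma_v^2/(sigma_u^2+sigma_v^2) <= min(sigma_u^2, sigma_v^2).
    Both variances zero (noiseless) returns 0.5 by convention.
    """
    if sigma2_u < 0 or sigma2_v < 0:
        raise ValueError("error variances must be nonnegative")
    total = sigma2_u + sigma2_v
    if total == 0:
        return 0.5
    return sigma2_v / total


def combine(W, M_star, gamma: float) -> np.ndarray:
    """Composite series gamma*W + (1-gamma)*M_star."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    W = np.asarray(W, dtype=float)
    M_star = np.asarray(M_star, dtype=float)
    return gamma * W + (1.0 - gamma) * M_star
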