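"""Skew-normal distribution mathematics.

The skew-normal (SN) family extends the normal with a shape parameter
``alpha``: the standardized density is ``2*phi(z)*Phi(alpha*z)``, so
``alpha = 0`` recovers the normal.  Location/scale versions are written
``X = xi + omega*Z``.  The family is the working model for skewed
biomarker distributions throughout this package: its first three moments
have closed forms in ``delta = alpha / sqrt(1 + alpha**2)``, which makes
method-of-moments fitting a one-dimensional root-find.

Density, CDF and quantiles are evaluated through
:mod:`scipy.stats.skewnorm`; the moment maps, their inversion, and the
sampling representation used by the simulation harness live here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import skewnorm as _sp_skewnorm

__all__ = [
    "SNParams",
    "SNMoments",
    "SKEWNESS_SUP",
    "SkewnessInfeasibleWarning",
    "sn_pdf",
    "sn_cdf",
    "sn_quantile",
    "sn_moments",
    "sn_from_moments",
    "sn_rvs",
    "delta_from_alpha",
    "alpha_from_delta",
    "skewness_from_delta",
]

# sup of |skewness| over the SN family, attained as |alpha| -> inf (delta -> 1):
# ((4-pi)/2) * (sqrt(2/pi))**3 / (1 - 2/pi)**1.5
SKEWNESS_SUP = 0.5 * (4.0 - math.pi) * (math.sqrt(2.0 / math.pi)) ** 3 / (1.0 - 2.0 / math.pi) ** 1.5

_DELTA_CLAMP = 1.0 - 1e-6


class SkewnessInfeasibleWarning(UserWarning):
    """Sample skewness at or beyond the SN supremum; fit clamped to the boundary."""


def _check_finite(*vals: float) -> None:
    for v in vals:
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite input")


@dataclass(frozen=True)
class SNParams:
    """Location ``xi``, scale ``omega`` (> 0) and shape ``alpha`` of a skew-normal."""

    xi: float
    omega: float
    alpha: float

    def __post_init__(self) -> None:
        _check_finite(self.xi, self.omega, self.alpha)
        if self.omega <= 0:
            raise ValueError(f"omega must be positive, got {self.omega}")

    @property
    def delta(self) -> float:
        return delta_from_alpha(self.alpha)


@dataclass(frozen=True)
class SNMoments:
    """Mean, variance and standardized skewness of a skew-normal.

    Feasible skewness is bounded: |skewness| < 0.99528 (the supremum as
    |alpha| grows without bound).
    """

    mean: float
    variance: float
    skewness: float

    def __post_init__(self) -> None:
        _check_finite(self.mean, self.variance, self.skewness)
        if self.variance <= 0:
            raise ValueError(f"variance must be positive, got {self.variance}")


def delta_from_alpha(alpha: float) -> float:
    return alpha / math.sqrt(1.0 + alpha * alpha)


def alpha_from_delta(delta: float) -> float:
    if abs(delta) >= 1.0:
        raise ValueError("delta must lie in (-1, 1)")
    return delta / math.sqrt(1.0 - delta * delta)


def skewness_from_delta(delta: float) -> float:
    """Closed-form standardized third moment; strictly increasing in delta."""
    b = delta * math.sqrt(2.0 / math.pi)
    return 0.5 * (4.0 - math.pi) * b**3 / (1.0 - b * b) ** 1.5


def sn_pdf(x, p: SNParams):
    """Density ``(2/omega) * phi((x-xi)/omega) * Phi(alpha*(x-xi)/omega)``."""
    x = np.asarray(x, dtype=float)
    _check_finite(x)
    return _sp_skewnorm.pdf(x, p.alpha, loc=p.xi, scale=p.omega)


def sn_cdf(x, p: SNParams):
    """CDF, evaluated via Owen's T function."""
    x = np.asarray(x, dtype=float)
    _check_finite(x)
    return _sp_skewnorm.cdf(x, p.alpha, loc=p.xi, scale=p.omega)


def sn_quantile(q, p: SNParams):
    """Quantile function (inverse CDF)."""
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("quantile levels must lie in [0, 1]")
    return _sp_skewnorm.ppf(q, p.alpha, loc=p.xi, scale=p.omega)


def sn_moments(p: SNParams) -> SNMoments:
    """Mean, variance, skewness of ``SN(xi, omega, alpha)``.

    mean = xi + omega*delta*sqrt(2/pi); variance = omega^2*(1 - 2*delta^2/pi);
    skewness depends on delta only.
    """
    d = p.delta
    b = d * math.sqrt(2.0 / math.pi)
    mean = p.xi + p.omega * b
    variance = p.omega**2 * (1.0 - b * b)
    return SNMoments(mean=mean, variance=variance, skewness=skewness_from_delta(d))


def sn_from_moments(m: SNMoments, *, clamp: bool = True) -> tuple[SNParams, bool]:
    """Invert :func:`sn_moments` by solving the skewness equation for delta.

    The standardized skewness is strictly increasing in delta, so a
    bracketed root on |delta| in (0, 1) is unique; the sign of delta is the
    sign of the skewness.  Returns ``(params, clamped)`` where ``clamped``
    flags a skewness at or beyond the feasible supremum (|skew| >=
    0.99528 - 1e-6): with ``clamp=True`` the boundary fit at
    delta = +/-(1 - 1e-6) is returned with a warning, otherwise a
    ``ValueError`` is raised.
    """
    skew = m.skewness
    clamped = False
    if abs(skew) >= skewness_from_delta(_DELTA_CLAMP):
        if not clamp:
            raise ValueError(
                f"skewness {skew} at or beyond the skew-normal supremum {SKEWNESS_SUP:.5f}"
            )
        warnings.warn(
            f"skewness {skew:.5f} infeasible for a skew-normal "
            f"(sup {SKEWNESS_SUP:.5f}); clamping to the boundary",
            SkewnessInfeasibleWarning,
            stacklevel=2,
        )
        d = math.copysign(_DELTA_CLAMP, skew)
        clamped = True
    elif skew == 0.0:
        d = 0.0
    else:
        a_skew = abs(skew)
        sol = optimize.brentq(
            lambda dd: skewness_from_delta(dd) - a_skew, 0.0, _DELTA_CLAMP, xtol=1e-14
        )
        d = math.copysign(sol, skew)
    b = d * math.sqrt(2.0 / math.pi)
    omega = math.sqrt(m.variance / (1.0 - b * b))
    xi = m.mean - omega * b
    return SNParams(xi=xi, omega=omega, alpha=alpha_from_delta(d)), clamped


def sn_rvs(p: SNParams, n: int, seed) -> np.ndarray:
    """Draw ``n`` variates via ``Z = delta*|N1| + sqrt(1-delta^2)*N2``.

    ``seed`` may be an int or a ``numpy.random.Generator``; a fixed int
    seed reproduces the sample exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    d = p.delta
    n1 = rng.standard_normal(n)
    n2 = rng.standard_normal(n)
    z = d * np.abs(n1) + math.sqrt(1.0 - d * d) * n2
    return p.xi + p.omega * z
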