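"""Binormal accuracy theory and correction-for-attenuation (de-attenuation).

Under binormal case/control biomarker distributions with additive normal
assay error, the observed (error-prone) AUC is an attenuated version of
the true AUC, and the attenuation is governed by the intra/inter
individual variance ratio ``lambda^2 = sigma_u^2 / sigma_x^2`` (or its
unequal-variance generalization ``lambda*^2``).  The de-attenuation maps
act on the probit scale:

    AUC_x = Phi( Phi^{-1}(AUC_w) * sqrt(1 + lambda^2) )
    Se_x  = 1 - Phi( Phi^{-1}(1 - Se_w) * sqrt(1 + lambda_1^2) )
    Sp_x  = Phi( Phi^{-1}(Sp_w) * sqrt(1 + lambda_0^2) )

with group-specific ratios for sensitivity (cases, group 1) and
specificity (controls, group 0).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "BinormalGroups",
    "NoiseRatios",
    "binormal_auc",
    "attenuate_auc",
    "correct_auc",
    "correct_sensitivity",
    "correct_specificity",
    "noise_ratios",
]

_CLIP = 1e-10


@dataclass(frozen=True)
class BinormalGroups:
    """Means, true-biomarker SDs and error SDs for controls (0) and cases (1)."""

    mu0: float
    mu1: float
    sigma_x0: float
    sigma_x1: float
    sigma_u0: float = 0.0
    sigma_u1: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_x0 <= 0 or self.sigma_x1 <= 0:
            raise ValueError("true-biomarker SDs must be positive")
        if self.sigma_u0 < 0 or self.sigma_u1 < 0:
            raise ValueError("error SDs must be nonnegative")
        if self.mu1 < self.mu0:
            warnings.warn(
                "mu1 < mu0: by convention larger biomarker values indicate disease",
                UserWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class NoiseRatios:
    """Intra/inter variance ratios.

    ``lambda2`` is the pooled ratio sigma_u^2/sigma_x^2, ``lambda2_star``
    the unequal-variance (Reiser) ratio
    (sigma_u0^2+sigma_u1^2)/(sigma_x0^2+sigma_x1^2), and ``lambda2_0`` /
    ``lambda2_1`` the group-specific ratios used for specificity and
    sensitivity corrections.
    """

    lambda2: float
    lambda2_star: float
    lambda2_0: float
    lambda2_1: float

    def __post_init__(self) -> None:
        for v in (self.lambda2, self.lambda2_star, self.lambda2_0, self.lambda2_1):
            if v < 0:
                raise ValueError("variance ratios must be nonnegative")


def _probit(p: float, clip: bool) -> float:
    if clip:
        p = min(max(p, _CLIP), 1.0 - _CLIP)
    if not 0.0 < p < 1.0:
        raise ValueError(f"probability must lie strictly in (0, 1), got {p}")
    return norm.ppf(p)


def binormal_auc(g: BinormalGroups, with_error: bool = False) -> float:
    """AUC = Phi( (mu1-mu0) / sqrt(sigma_x0^2 + sigma_x1^2 [+ error var]) )."""
    total = g.sigma_x0**2 + g.sigma_x1**2
    if with_error:
        total += g.sigma_u0**2 + g.sigma_u1**2
    if total <= 0:
        raise ValueError("zero total variance")
    return float(norm.cdf((g.mu1 - g.mu0) / math.sqrt(total)))


def attenuate_auc(auc_x: float, ratio: float) -> float:
    """Forward map: the AUC observed on an error-prone series.

    ``Phi( Phi^{-1}(auc_x) / sqrt(1 + ratio) )`` — the algebraic inverse of
    :func:`correct_auc`.
    """
    if ratio < 0:
        raise ValueError("variance ratio must be nonnegative")
    return float(norm.cdf(_probit(auc_x, clip=False) / math.sqrt(1.0 + ratio)))


def correct_auc(auc_w: float, ratio: float, *, clip: bool = False) -> float:
    """De-attenuate an observed AUC: ``Phi( Phi^{-1}(auc_w)*sqrt(1+ratio) )``.

    ``ratio`` is lambda^2 (equal group variances) or lambda*^2 (Reiser).
    ``clip`` nudges boundary probabilities inward; meant for bootstrap
    resamples only — direct calls on {0, 1} are rejected.
    """
    if ratio < 0:
        raise ValueError("variance ratio must be nonnegative")
    return float(norm.cdf(_probit(auc_w, clip) * math.sqrt(1.0 + ratio)))


def correct_sensitivity(se_w: float, lambda2_1: float, *, clip: bool = False) -> float:
    """De-attenuate sensitivity with the case-group ratio lambda_1^2."""
    if lambda2_1 < 0:
        raise ValueError("variance ratio must be nonnegative")
    return float(1.0 - norm.cdf(_probit(1.0 - se_w, clip) * math.sqrt(1.0 + lambda2_1)))


def correct_specificity(sp_w: float, lambda2_0: float, *, clip: bool = False) -> float:
    """De-attenuate specificity with the control-group ratio lambda_0^2."""
    if lambda2_0 < 0:
        raise ValueError("variance ratio must be nonnegative")
    return float(norm.cdf(_probit(sp_w, clip) * math.sqrt(1.0 + lambda2_0)))


def noise_ratios(moments0, moments1) -> NoiseRatios:
    """Variance ratios from per-group moment estimates.

    Accepts any objects exposing ``sigma2_x``/``sigma2_u`` (e.g.
    :class:`snroc.measurement_model.GroupMoments`).  The pooled ``lambda2``
    averages variances across groups; the Reiser ``lambda2_star`` sums them.
    """
    sx0, sx1 = moments0.sigma2_x, moments1.sigma2_x
    su0, su1 = moments0.sigma2_u, moments1.sigma2_u
    if sx0 <= 0 or sx1 <= 0:
        raise ValueError("nonpositive true-biomarker variance estimate: not identified")
    return NoiseRatios(
        lambda2=(su0 + su1) / (sx0 + sx1),
        lambda2_star=(su0 + su1) / (sx0 + sx1),
        lambda2_0=su0 / sx0,
        lambda2_1=su1 / sx1,
    )
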