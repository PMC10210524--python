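"""Recover a skewed latent biomarker distribution from a noisy assay.

Draws a skew-normal biomarker X (shape sqrt(6), standardized), observes
W = X + U with unit-variance normal error, and fits the error-corrected
skew-normal by the first three moments of W with the error variance
subtracted from the variance equation.  The naive fit of W ignores the
error and is biased toward symmetry.
"""

import math

import numpy as np

from snroc import SNParams, fit_group_sn, sn_moments, sn_rvs

shape = math.sqrt(6)
base = sn_moments(SNParams(0.0, 1.0, shape))
omega = 1.0 / math.sqrt(base.variance)
true_params = SNParams(xi=3.0 - base.mean * omega, omega=omega, alpha=shape)

rng = np.random.default_rng(7)
n = 50_000
x = sn_rvs(true_params, n, rng)
w = x + rng.normal(0.0, 1.0, n)

corrected = fit_group_sn(w, sigma2_u=1.0)
naive = fit_group_sn(w, sigma2_u=0.0)

print(f"true:      xi={true_params.xi:7.4f} omega={true_params.omega:6.4f} alpha={true_params.alpha:6.4f}")
p = corrected.params
print(f"corrected: xi={p.xi:7.4f} omega={p.omega:6.4f} alpha={p.alpha:6.4f}")
p = naive.params
print(f"naive:     xi={p.xi:7.4f} omega={p.omega:6.4f} alpha={p.alpha:6.4f}")
print(
    "\nThe corrected fit recovers the latent location/scale/shape; the naive "
    "fit inflates the scale (it absorbs the error variance) and shrinks the "
    "shape toward 0 because added symmetric noise dilutes skewness."
)
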