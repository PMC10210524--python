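# Methods

## Model and assumptions

Case/control subjects carry a latent biomarker `X` with group means
`μ_{x,0} ≤ μ_{x,1}` (larger values indicate disease, by convention) and
two observable assay series

```
W = X + U,              E(U|X) = 0,  var(U) = σ_u²
M = α₀ + α₁ X + V,      E(V|X) = 0,  var(V) = σ_v²
```

with `X`, `U`, `V` mutually independent and errors normal. Accuracy is
summarized by AUC = P(X₁ > X₀), and by sensitivity P(X ≥ c | case) and
specificity P(X ≤ c | control) at a cutoff `c` fixed in advance. Three
identification regimes are supported: replicates (`α = (0,1)`,
`σ_u = σ_v`), an unbiased pair (`α = (0,1)`, different error SDs — e.g.
clinical vs research assay), and a biased linear `M` (general `α`),
which additionally requires error variances equal across disease groups
because its calibration is identified through `Y`.

## Estimators

* **Naive** — empirical Mann–Whitney AUC (midranks, half-weight ties)
  and empirical Se/Sp of an error-prone series, no correction.
* **CFA** — probit-scale de-attenuation. AUC uses the unequal-variance
  ratio `λ*² = (σ_{u,0}²+σ_{u,1}²)/(σ_{x,0}²+σ_{x,1}²)`; Se and Sp use
  the group-specific ratios `λ₁²`, `λ₀²`. Applied to W, to M (after
  rescaling when calibrated), or to the minimum-variance composite
  `γW + (1−γ)M*` with `γ = σ_v²/(σ_u²+σ_v²)`, whose error variance is
  `σ_u²σ_v²/(σ_u²+σ_v²) ≤ min(σ_u², σ_v²)`.
* **SN correction** — per disease group, match the skew-normal
  `SN(ξ, ω, α)` to (mean of W, var of W minus the error variance, third
  central moment of W standardized by the *corrected* variance). All
  central moments use the divisor-n convention, which is the reading of
  the estimating equations under which the moment system has the closed
  solution used here. Accuracy measures are computed from the fitted
  group distributions; in the pipeline the composite series (with its
  composite error variance) feeds the fit by default, with a W-only
  switch.

Under the unbiased-pair model all variance components are estimated
within each disease group separately; under the linear-M model the
error variances are pooled across groups (an identification
requirement), while the biomarker variances stay group-specific. The
combination weight γ always uses the size-weighted pooled error
variances.

## Skew-normal numerics

* Moments: mean `ξ + ωδ√(2/π)`, variance `ω²(1 − 2δ²/π)`, skewness
  `((4−π)/2)(δ√(2/π))³/(1−2δ²/π)^{3/2}` with `δ = α/√(1+α²)`. The
  skewness map is strictly increasing in δ, so moment inversion is a
  bracketed scalar root-find on δ ∈ (0, 1) (Brent, xtol 1e-14) with the
  sign taken from the sample skewness; parameterizing in δ removes the
  multiple-root ambiguity of solving in α directly.
* Feasibility: |skewness| is bounded by ≈0.99527 over the family. A
  sample skewness at or beyond 0.99528 − 1e-6 yields the boundary fit
  at δ = ±(1 − 1e-6) with a warning and a `clamped` flag instead of a
  failure — important inside bootstrap loops, where resampled third
  moments routinely stray past the boundary. The log-normal scenario
  (population skewness ≈0.95) sits near but inside the boundary.
* pdf/cdf/quantiles are delegated to `scipy.stats.skewnorm` (Owen's-T
  based CDF); sampling uses the representation
  `Z = δ|N₁| + √(1−δ²)N₂` under a `numpy` Generator for reproducible
  substreams.
* ROC/AUC from fitted distributions: 2001 cutoffs spanning the union of
  the groups' 1e-6…1−1e-6 quantile ranges, trapezoidal AUC with (0,0)
  and (1,1) appended; agrees with direct quadrature of `f₁·F₀` to
  2e-4, and doubling the grid moves the value by < 5e-5.
* A numerical caveat: near α = 0 the skewness map is cubic in δ, so the
  fitted shape converges at the cube root of the skewness sampling
  noise (typical |α̂| ≈ 0.2 even at n = 10⁶ normal draws). The fitted
  *distribution* (mean, variance, skewness) is stable; only the α
  coordinate is ill-conditioned at the symmetric point.

## Synthetic data

The generator emulates the two-assay case/control design: exact
`⌈n·rate⌉` cases (deterministic allocation, no binomial jitter —
reduces Monte-Carlo variance), control mean 3 and SD 1, case mean
shifted by ln(3.2), errors normal. Families: normal; skew-normal with
configurable shape (default 6) standardized to mean 3/SD 1 before
shifting; log-normal as exp of N(1, 0.3²) controls and N(1.5, 0.3²)
cases. Defaults (n = 300, 50% disease rate, σ_u = σ_v = 1, 500
replicates) are the study conditions of the replicate-error design;
presets T1 (σ = 0.71), T2 (1.22), T3 (1, 1), T4 (0.2, 1) and T5
(linear M with α = (0.2, 0.8), σ = 1) name the other designs.

Population truths: normal AUC `Φ(ln 3.2/√2) = 0.7946`; log-normal AUC
`Φ(0.5/(0.3√2)) = 0.8807` (the log transform is monotone, so the AUC is
the binormal one on the log scale — the harness reports this analytic
value); skew-normal AUC by quadrature (0.8061 at shape 6, 0.8004 at
shape √6). Simulation cutoffs are fixed per scenario at the population
min-distance ROC point of the *true* distributions, found on a
4001-point grid spanning the 1e-6…1−1e-6 quantile hull; cutoff rules
always return grid members, and data-driven rules search the sorted
unique observed values.

What the generator does not emulate: real assay panels have detection
limits, zero inflation, batch effects, and error variances that scale
with the measured level. Passing tests show the estimators behave as
designed under additive homoscedastic normal error with the stated
families — not that they are robust to those departures.

## Inference

Bootstrap: stratified resampling (cases and controls separately, group
sizes preserved exactly), B = 200 by default, per-resample substreams
spawned from one master seed. SE is the SD of resample estimates; the
default CI is normal-theory (estimate ± z·SE, truncated to [0, 1]),
with percentile intervals available — which construction produced a
coverage number is recorded by the caller's spec. Inside resamples,
probabilities are clipped to [1e-10, 1−1e-10] before the probit and
infeasible skewness falls back to the clamped boundary fit; direct
calls keep strict semantics. A resample on which the pipeline fails is
skipped and counted; more than 20% failures aborts the bootstrap.

## Design choices and limitations

* Negative error-variance estimates are clamped to 0 with a warning
  ("no detectable error"); a nonpositive biomarker-variance estimate is
  a fatal identification error.
* Variance/covariance estimates use divisor n throughout, matching the
  plug-in moment displays; the difference from n−1 is O(1/n).
* The Se/Sp de-attenuation is an asymptotic approximation; no
  finite-sample correction is applied.
* The SN correction is a working-model estimator: it is consistent when
  the latent biomarker is skew-normal (and exactly normal as a special
  case) but not for arbitrary distributions; for the log-normal family
  it is an approximation that empirically carries small bias at these
  designs.
* Reported simulation problem sizes: bias/SD columns use the full 500
  replicates of n = 300; bootstrap ASE/CP columns are optional and off
  by default because they multiply cost by B.
* Real two-assay study data are not bundled; the analysis workflow is
  demonstrated on synthetic studies (`examples/two_assay_analysis.py`).
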