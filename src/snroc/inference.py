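"""Bootstrap standard errors, confidence intervals, and coverage bookkeeping.

Resampling is stratified: cases and controls are resampled separately
with replacement, so every resample preserves n0 and n1 and the whole
estimation pipeline — including the error-variance identification — is
repeated per resample.  Seeding uses one master seed with per-resample
substreams spawned deterministically, so serial and parallel execution
agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .roc_empirical import AccuracyEstimate

__all__ = ["BootstrapSpec", "InferenceError", "bootstrap", "coverage"]


class InferenceError(RuntimeError):
    """Too many resamples failed for the bootstrap to be trustworthy."""


@dataclass(frozen=True)
class BootstrapSpec:
    """Bootstrap configuration: replicate count, seed, CI level and method."""

    n_boot: int = 200
    seed: int = 0
    ci_level: float = 0.95
    method: str = "normal"

    def __post_init__(self) -> None:
        if self.n_boot < 50:
            raise ValueError("n_boot must be >= 50 for SE use")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.method not in ("normal", "percentile"):
            raise ValueError("method must be 'normal' or 'percentile'")


_MEASURES = ("auc", "sensitivity", "specificity")


def bootstrap(estimator, Y, W, M, spec: BootstrapSpec) -> AccuracyEstimate:
    """Stratified bootstrap of an accuracy-estimation pipeline.

    ``estimator(Y, W, M) -> AccuracyEstimate`` is recomputed on each
    resample.  The point estimate is the estimator on the original data;
    SEs are SDs of the resample estimates; CIs follow ``spec.method``
    (normal-theory estimate +/- z*SE, truncated to [0, 1], or
    percentile).  Individual resample failures are skipped and counted;
    more than 20% failures raises :class:`InferenceError`.
    """
    Y = np.asarray(Y, dtype=float)
    W = np.asarray(W, dtype=float)
    M = np.asarray(M, dtype=float)
    idx0 = np.flatnonzero(Y == 0)
    idx1 = np.flatnonzero(Y == 1)
    if idx0.size == 0 or idx1.size == 0:
        raise ValueError("both disease groups must be nonempty")

    point = estimator(Y, W, M)

    master = np.random.SeedSequence(spec.seed)
    streams = master.spawn(spec.n_boot)
    draws: dict[str, list[float]] = {m: [] for m in _MEASURES}
    failures = 0
    for child in streams:
        rng = np.random.default_rng(child)
        r0 = rng.choice(idx0, size=idx0.size, replace=True)
        r1 = rng.choice(idx1, size=idx1.size, replace=True)
        take = np.concatenate([r0, r1])
        try:
            est = estimator(Y[take], W[take], M[take])
        except Exception:
            failures += 1
            continue
        for m in _MEASURES:
            draws[m].append(getattr(est, m))
    n_ok = spec.n_boot - failures
    if failures > 0.2 * spec.n_boot:
        raise InferenceError(
            f"{failures}/{spec.n_boot} bootstrap resamples failed"
        )

    z = norm.ppf(0.5 + spec.ci_level / 2.0)
    ses, cis = {}, {}
    for m in _MEASURES:
        arr = np.asarray(draws[m], dtype=float)
        se = float(arr.std(ddof=1)) if n_ok > 1 else 0.0
        ses[m] = se
        est_val = getattr(point, m)
        if spec.method == "normal":
            lo, hi = est_val - z * se, est_val + z * se
        else:
            a = (1.0 - spec.ci_level) / 2.0
            lo, hi = np.quantile(arr, [a, 1.0 - a]) if n_ok else (est_val, est_val)
        cis[m] = (max(float(lo), 0.0), min(float(hi), 1.0))

    return AccuracyEstimate(
        auc=point.auc,
        sensitivity=point.sensitivity,
        specificity=point.specificity,
        cutoff=point.cutoff,
        se_auc=ses["auc"],
        se_se=ses["sensitivity"],
        se_sp=ses["specificity"],
        ci={**cis, "n_failed": failures},
    )


def coverage(true_value: float, cis) -> float:
    """Fraction of (lo, hi) intervals that contain ``true_value``."""
    cis = list(cis)
    if not cis:
        raise ValueError("need at least one interval")
    hits = sum(1 for lo, hi in cis if lo <= true_value <= hi)
    return hits / len(cis)
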