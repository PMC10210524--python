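"""Empirical (uncorrected) accuracy measures and cutoff-selection rules.

The empirical AUC is the Mann–Whitney statistic with half-weight for
ties; cutoff rules operate on sensitivity/specificity functions evaluated
over a grid, so the same rules serve both theoretical distributions and
data-driven step functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "AccuracyEstimate",
    "empirical_auc",
    "empirical_sensitivity",
    "empirical_specificity",
    "min_distance_cutoff",
    "youden_cutoff",
    "constrained_specificity_cutoff",
    "kde_bandwidth",
]


@dataclass
class AccuracyEstimate:
    """AUC, sensitivity and specificity at a cutoff, with optional bootstrap SEs/CIs."""

    auc: float
    sensitivity: float
    specificity: float
    cutoff: float
    se_auc: float | None = None
    se_se: float | None = None
    se_sp: float | None = None
    ci: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("auc", "sensitivity", "specificity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def empirical_auc(cases, controls) -> float:
    """Mann–Whitney AUC: mean over all case/control pairs of
    1(case > control) + 0.5 * 1(case == control).

    Computed via midranks in O(n log n); identical to the brute-force pair
    enumeration.
    """
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    n1, n0 = cases.size, controls.size
    if n1 == 0 or n0 == 0:
        raise ValueError("both groups must be nonempty")
    ranks = rankdata(np.concatenate([cases, controls]))
    r1 = ranks[:n1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def empirical_sensitivity(cases, cutoff: float) -> float:
    """Fraction of cases at or above the cutoff (true-positive rate)."""
    cases = np.asarray(cases, dtype=float)
    if cases.size == 0:
        raise ValueError("empty case group")
    return float(np.mean(cases >= cutoff))


def empirical_specificity(controls, cutoff: float) -> float:
    """Fraction of controls below the cutoff (true-negative rate)."""
    controls = np.asarray(controls, dtype=float)
    if controls.size == 0:
        raise ValueError("empty control group")
    return float(np.mean(controls < cutoff))


def _eval_grid(se_fn, sp_fn, grid):
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty cutoff grid")
    se = np.asarray([se_fn(c) for c in grid], dtype=float)
    sp = np.asarray([sp_fn(c) for c in grid], dtype=float)
    return grid, se, sp


def min_distance_cutoff(se_fn, sp_fn, grid) -> float:
    """Cutoff whose ROC point is closest to the perfect-test corner (0, 1).

    Minimizes (1-Se)^2 + (1-Sp)^2 over the grid; ties resolve to the
    smallest cutoff.
    """
    grid, se, sp = _eval_grid(se_fn, sp_fn, grid)
    dist = (1.0 - se) ** 2 + (1.0 - sp) ** 2
    return float(grid[int(np.argmin(dist))])


def youden_cutoff(se_fn, sp_fn, grid) -> float:
    """Cutoff maximizing Youden's index Se + Sp - 1; smallest-cutoff tie rule."""
    grid, se, sp = _eval_grid(se_fn, sp_fn, grid)
    j = se + sp - 1.0
    return float(grid[int(np.argmax(j))])


def constrained_specificity_cutoff(se_fn, sp_fn, grid, min_se: float) -> float:
    """Best specificity subject to sensitivity >= ``min_se``.

    Raises if no grid cutoff attains the sensitivity floor.
    """
    if not 0.0 <= min_se <= 1.0:
        raise ValueError("min_se must lie in [0, 1]")
    grid, se, sp = _eval_grid(se_fn, sp_fn, grid)
    ok = se >= min_se
    if not np.any(ok):
        raise ValueError(f"no cutoff attains sensitivity >= {min_se}")
    sp_masked = np.where(ok, sp, -np.inf)
    return float(grid[int(np.argmax(sp_masked))])


def kde_bandwidth(sample, factor: float = 2.0) -> float:
    """Kernel-density bandwidth ``factor * sd(sample) * n**(-1/3)``.

    ``factor`` 2 is the primary choice, 4 a wider alternative for
    visual comparison.  A zero-SD sample yields bandwidth 0 (degenerate).
    """
    sample = np.asarray(sample, dtype=float)
    if sample.size < 2:
        raise ValueError("need at least 2 observations")
    sd = float(np.std(sample, ddof=1))
    return factor * sd * sample.size ** (-1.0 / 3.0)
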