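"""Study-table I/O and the two-assay analysis workflow.

A study table has one row per subject: an id, a binary disease indicator
``y``, a primary (clinical) assay ``w`` and optionally a secondary
(research) assay ``m``.  Files are comma-separated UTF-8 with a header
row.  The ``log1p_div10`` transform — log(value + 1)/10 — is the
conventional rescaling for heavy-tailed antigen assays such as CA19-9;
it changes cutoffs but not AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import BootstrapSpec, bootstrap
from .roc_empirical import (
    constrained_specificity_cutoff,
    min_distance_cutoff,
    youden_cutoff,
    empirical_sensitivity,
    empirical_specificity,
)
from .simulation import ESTIMATORS, make_estimator

logger = logging.getLogger("snroc")

__all__ = ["StudyTable", "read_study", "analyze", "write_report"]

TRANSFORMS = {
    "none": lambda x: x,
    "log1p_div10": lambda x: np.log1p(x) / 10.0,
}


@dataclass
class StudyTable:
    """Parsed case/control biomarker data."""

    subject_id: np.ndarray
    y: np.ndarray
    w: np.ndarray
    m: np.ndarray | None

    @property
    def n0(self) -> int:
        return int(np.sum(self.y == 0))

    @property
    def n1(self) -> int:
        return int(np.sum(self.y == 1))


def read_study(
    path,
    y_col: str = "Y",
    w_col: str = "W",
    m_col: str | None = "M",
    id_col: str | None = None,
    transform: str = "none",
) -> StudyTable:
    """Read a delimited study file into a :class:`StudyTable`.

    Rows with missing ``y`` are dropped (logged); a non-binary ``y``
    raises with the offending row index.  ``transform`` applies to both
    assay columns.
    """
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}; choose from {sorted(TRANSFORMS)}")
    df = pd.read_csv(path)
    for col in [y_col, w_col] + ([m_col] if m_col else []):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path} (has {list(df.columns)})")
    n_missing = int(df[y_col].isna().sum())
    if n_missing:
        logger.info("dropping %d rows with missing %s", n_missing, y_col)
        df = df.dropna(subset=[y_col])
    bad = ~df[y_col].isin([0, 1])
    if bad.any():
        raise ValueError(
            f"non-binary {y_col} values at rows {df.index[bad].tolist()[:10]}"
        )
    y = df[y_col].to_numpy(int)
    if not (np.any(y == 0) and np.any(y == 1)):
        raise ValueError("both disease groups must be nonempty")
    f = TRANSFORMS[transform]
    w = f(df[w_col].to_numpy(float))
    m = f(df[m_col].to_numpy(float)) if m_col else None
    ids = (
        df[id_col].astype(str).to_numpy()
        if id_col
        else df.index.astype(str).to_numpy()
    )
    logger.info("read %d subjects: n0=%d, n1=%d", y.size, int((y == 0).sum()), int((y == 1).sum()))
    return StudyTable(subject_id=ids, y=y, w=w, m=m)


def _choose_cutoff(table: StudyTable, rule: str) -> float:
    """Data-driven cutoff on the W series over its sorted unique values."""
    grid = np.unique(table.w)
    cases, controls = table.w[table.y == 1], table.w[table.y == 0]
    se_fn = lambda c: empirical_sensitivity(cases, c)
    sp_fn = lambda c: empirical_specificity(controls, c)
    if rule == "min_distance":
        return min_distance_cutoff(se_fn, sp_fn, grid)
    if rule == "youden":
        return youden_cutoff(se_fn, sp_fn, grid)
    if rule.startswith("constrained_se:"):
        min_se = float(rule.split(":", 1)[1])
        return constrained_specificity_cutoff(se_fn, sp_fn, grid, min_se)
    raise ValueError(f"unknown cutoff rule {rule!r}")


def analyze(
    table: StudyTable,
    model: str = "unbiased_pair",
    cutoff_rule: str = "min_distance",
    boot: BootstrapSpec | None = None,
    estimators=ESTIMATORS,
) -> pd.DataFrame:
    """Estimate AUC/Se/Sp for each requested estimator on a study table.

    ``model`` is ``unbiased_pair`` (both assays unbiased for X, possibly
    different error SDs; replicates are the equal-SD special case) or
    ``linear_m`` (M is a biased linear measure, calibrated through Y).
    All estimators except the naive one need both assay series.
    """
    if table.m is None:
        raise ValueError("two assay series are required for error-corrected estimation")
    if np.mean(table.w[table.y == 1]) < np.mean(table.w[table.y == 0]):
        logger.warning(
            "cases have lower mean W than controls: check marker orientation"
        )
    cutoff = _choose_cutoff(table, cutoff_rule)
    logger.info("cutoff rule %s -> c = %.6g (n0=%d, n1=%d)", cutoff_rule, cutoff, table.n0, table.n1)
    rows = []
    for name in estimators:
        fn = make_estimator(name, cutoff, model)
        try:
            if boot is not None:
                est = bootstrap(fn, table.y, table.w, table.m, boot)
            else:
                est = fn(table.y, table.w, table.m)
        except Exception as exc:
            raise RuntimeError(f"estimator {name} failed: {exc}") from exc
        rows.append(
            {
                "estimator": name,
                "cutoff": cutoff,
                "auc": est.auc,
                "se_auc": est.se_auc,
                "sensitivity": est.sensitivity,
                "se_sensitivity": est.se_se,
                "specificity": est.specificity,
                "se_specificity": est.se_sp,
            }
        )
    return pd.DataFrame(rows)


def write_report(df: pd.DataFrame, path) -> None:
    """Write a results table as CSV with full float precision."""
    df.to_csv(path, index=False, float_format="%.10g")
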