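"""Covariate balance before and after matching: standardized differences.

The standardized mean difference (SMD) is the scale-free between-group
difference conventionally used to judge matching quality; |SMD| < 0.1
is the usual adequacy threshold.  "Before" compares ever- versus
never-transplanted subjects on baseline covariates; "after" compares
the transplant arm with its matched controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable, design_matrix
from .matching import MatchedCohort


def smd_continuous(mean1, sd1, mean2, sd2) -> float:
    """Signed SMD for a continuous covariate:
    (mean1 - mean2) / sqrt((sd1^2 + sd2^2) / 2)."""
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    denom = np.sqrt((sd1 ** 2 + sd2 ** 2) / 2.0)
    if denom == 0:
        if mean1 == mean2:
            return 0.0
        warnings.warn("zero variance in both groups with differing means; "
                      "SMD is infinite", stacklevel=2)
        return float(np.inf if mean1 > mean2 else -np.inf)
    return float((mean1 - mean2) / denom)


def smd_binary(p1, p2) -> float:
    """Signed SMD for a binary covariate:
    (p1 - p2) / sqrt((p1(1-p1) + p2(1-p2)) / 2)."""
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise ValueError("proportions must lie in [0, 1]")
    denom = np.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 2.0)
    if denom == 0:
        # both groups degenerate at the same value
        if p1 != p2:
            warnings.warn("degenerate proportions with differing values", stacklevel=2)
            return float(np.inf if p1 > p2 else -np.inf)
        return 0.0
    return float((p1 - p2) / denom)


@dataclass
class BalanceReport:
    """Per-covariate SMDs before/after matching plus mean |SMD| summary."""

    table: pd.DataFrame  # columns: name, type, smd_before, smd_after
    mean_abs_before: float
    mean_abs_after: float

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _smd_for(x1: np.ndarray, x2: np.ndarray, is_binary: bool) -> float:
    if is_binary:
        return smd_binary(float(np.mean(x1)), float(np.mean(x2)))
    return smd_continuous(float(np.mean(x1)), float(np.std(x1, ddof=1)),
                          float(np.mean(x2)), float(np.std(x2, ddof=1)))


def balance_report(cohort, matched: MatchedCohort, covariate_names) -> BalanceReport:
    """Standardized differences before and after matching.

    A covariate is treated as binary when its coded values lie in
    {0, 1}.  Results are invariant to subject ordering.
    """
    df = cohort.df if isinstance(cohort, CohortTable) else cohort
    X = design_matrix(df, covariate_names).set_index(df["id"])

    ever = df["tx_time"].notna().to_numpy()
    treated_ids = [p.treated_id for p in matched.pairs]
    control_ids = [p.control_id for p in matched.pairs]

    rows = []
    abs_before, abs_after = [], []
    for name in covariate_names:
        col = X[name]
        vals = col.to_numpy()
        is_binary = np.isin(np.unique(vals), (0.0, 1.0)).all()
        before = _smd_for(vals[ever], vals[~ever], is_binary)
        after = _smd_for(col.loc[treated_ids].to_numpy(),
                         col.loc[control_ids].to_numpy(), is_binary)
        rows.append((name, "binary" if is_binary else "continuous", before, after))
        abs_before.append(abs(before))
        abs_after.append(abs(after))
    table = pd.DataFrame(rows, columns=["name", "type", "smd_before", "smd_after"])
    return BalanceReport(table=table,
                         mean_abs_before=float(np.mean(abs_before)),
                         mean_abs_after=float(np.mean(abs_after)))
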