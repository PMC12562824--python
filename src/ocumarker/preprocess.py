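"""Cytokine exclusion/recoding rules and outlier handling.

Three rules precede any inference:

* analytes detected in fewer than ``min_detected`` samples are excluded;
* analytes where *every* strictly positive value is a 1.5*IQR outlier are
  recoded to a dichotomous "level > 0" variable (the continuous original is
  kept but flagged outlier-only and withheld from continuous analyses);
* for the multivariable stage, cells outside the 1.5*IQR fences of their
  variable are masked to missing (per-cell, preserving n for imputation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable, VariableMeta


@dataclass
class OutlierRule:
    """Tukey fence rule: fences at Q1 - k*IQR and Q3 + k*IQR.

    ``method`` is the quartile convention passed to :func:`numpy.percentile`
    (default linear interpolation between order statistics).
    """

    k: float = 1.5
    method: str = "linear"

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("fence multiplier k must be > 0")


@dataclass
class PreprocessReport:
    excluded: dict[str, str] = field(default_factory=dict)       # column -> reason code
    outlier_only: list[str] = field(default_factory=list)        # withheld continuous originals
    dichotomized: dict[str, str] = field(default_factory=dict)   # original -> recode column
    outlier_counts: dict[str, int] = field(default_factory=dict)
    n_cells_masked: int = 0

    def to_dict(self) -> dict:
        return {"excluded": self.excluded, "outlier_only": self.outlier_only,
                "dichotomized": self.dichotomized,
                "outlier_counts": self.outlier_counts,
                "n_cells_masked": self.n_cells_masked}


def detectability_filter(table: CohortTable, min_detected: int = 5
                         ) -> tuple[list[str], list[str]]:
    """Split analyte columns into (kept, excluded) by detected-sample count.

    An analyte detected in fewer than ``min_detected`` samples carries too
    little quantitative information and is excluded outright; non-analyte
    columns are never touched.
    """
    kept, excluded = [], []
    for col in table.analyte_columns():
        if int(table.detected(col).sum()) < min_detected:
            excluded.append(col)
        else:
            kept.append(col)
    return kept, excluded


def iqr_outliers(values: np.ndarray | pd.Series, rule: OutlierRule = OutlierRule()
                 ) -> tuple[float, float, np.ndarray]:
    """Fences and outlier mask under the Tukey rule.

    Quartiles are computed over non-missing values; the mask is False at
    missing positions.  Requires at least 4 non-missing values.
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[~np.isnan(arr)]
    if finite.size < 4:
        raise ValueError("need at least 4 non-missing values for IQR fences")
    q1, q3 = np.percentile(finite, [25, 75], method=rule.method)
    iqr = q3 - q1
    low, high = q1 - rule.k * iqr, q3 + rule.k * iqr
    with np.errstate(invalid="ignore"):
        mask = (arr < low) | (arr > high)
    mask &= ~np.isnan(arr)
    return float(low), float(high), mask


def dichotomize_if_all_positive_outliers(values: np.ndarray | pd.Series,
                                         rule: OutlierRule = OutlierRule()
                                         ) -> np.ndarray | None:
    """Recode to a 0/1 "level > 0" column iff every positive value is an outlier.

    Returns the dichotomous vector (NaN preserved) or None when the rule does
    not fire (no positive values, or any positive value inside the fences).
    """
    arr = np.asarray(values, dtype=float)
    with np.errstate(invalid="ignore"):
        positive = arr > 0
    positive &= ~np.isnan(arr)
    if not positive.any():
        return None
    _, _, outliers = iqr_outliers(arr, rule)
    if not np.all(outliers[positive]):
        return None
    out = np.where(np.isnan(arr), np.nan, positive.astype(float))
    return out


def mask_outliers_for_mva(table: CohortTable, rule: OutlierRule = OutlierRule()
                          ) -> tuple[CohortTable, int]:
    """Mask every continuous cell outside its variable's fences to missing.

    Dichotomous/nominal columns are untouched.  Idempotent: the surviving
    values all lie inside fences computed from themselves, which can only
    widen relative to the original fences.
    """
    out = table.copy()
    n_masked = 0
    for col in out.columns_by(scale="continuous"):
        vals = out.data[col].to_numpy(dtype=float)
        if (~np.isnan(vals)).sum() < 4:
            continue
        _, _, mask = iqr_outliers(vals, rule)
        n_masked += int(mask.sum())
        vals[mask] = np.nan
        out.data[col] = vals
    return out, n_masked


def run_preprocess(table: CohortTable, rule: OutlierRule = OutlierRule(),
                   min_detected: int = 5) -> tuple[CohortTable, PreprocessReport]:
    """Apply exclusion and recoding rules; return the analysis table + report.

    The returned table has under-detected analytes dropped and, for each
    outlier-only analyte, an added dichotomous ``<name>_pos`` recode; the
    continuous original is retained but listed in ``report.outlier_only`` so
    continuous analyses can withhold it.
    """
    report = PreprocessReport()
    out = table.copy()

    _, excluded = detectability_filter(out, min_detected)
    for col in excluded:
        report.excluded[col] = "detected_in_fewer_than_min_samples"
    out.data = out.data.drop(columns=excluded)
    for col in excluded:
        out.meta.pop(col, None)

    for col in out.analyte_columns():
        vals = out.data[col].to_numpy(dtype=float)
        if (~np.isnan(vals)).sum() < 4:
            continue
        _, _, mask = iqr_outliers(vals, rule)
        report.outlier_counts[col] = int(mask.sum())
        recode = dichotomize_if_all_positive_outliers(vals, rule)
        if recode is not None and int(mask.sum()) > 0:
            new_col = f"{col}_pos"
            out.data[new_col] = recode
            src = out.meta[col]
            out.meta[new_col] = VariableMeta(role="independent", scale="dichotomous",
                                             compartment=src.compartment)
            report.outlier_only.append(col)
            report.dichotomized[col] = new_col
    return out, report
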