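"""Two-group comparisons with normality-based routing, BH adjustment and
volcano-table construction.

Continuous variables are routed by the Shapiro-Wilk test: a two-sample
t-test (Welch by default) when both groups look normal at the chosen alpha,
a Wilcoxon rank-sum (Mann-Whitney U) otherwise.  Nominal variables use the
chi-square test on a 2x2 table when every cell holds at least five
observations, Fisher's exact test otherwise.  Descriptive summaries follow
the convention mean +/- SD for n > 30 or normal-looking samples, otherwise
median [IQR].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import CONTROL, GLAUCOMA, CohortTable, split_groups


@dataclass
class TestResult:
    variable: str
    test: str                 # t-test | wilcoxon | chi-square | fisher
    statistic: float
    p: float
    summary_a: str = ""
    summary_b: str = ""
    p_adj: float | None = None


def _summary(vals: np.ndarray, normal: bool) -> str:
    vals = np.asarray(vals, dtype=float)
    if vals.size > 30 or normal:
        return f"{vals.mean():.2f} ± {vals.std(ddof=1):.2f}"
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return f"{med:.2f} [{q1:.2f}–{q3:.2f}]"


def compare_continuous(x, y, alpha: float = 0.05, *, equal_var: bool = False,
                       variable: str = "") -> TestResult:
    """Shapiro-routed two-group comparison of a continuous variable."""
    x = np.asarray(pd.Series(x).dropna(), dtype=float)
    y = np.asarray(pd.Series(y).dropna(), dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError(f"{variable or 'variable'}: need >= 3 values per group")

    def _shapiro_p(v):
        if np.ptp(v) == 0:   # constant sample: certainly not normal-looking
            return 0.0
        return float(stats.shapiro(v).pvalue)

    norm_x, norm_y = _shapiro_p(x) > alpha, _shapiro_p(y) > alpha
    if norm_x and norm_y:
        if np.array_equal(x, y):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.ttest_ind(x, y, equal_var=equal_var)
        test = "t-test"
    else:
        method = ("exact" if max(x.size, y.size) <= 50
                  and np.unique(np.concatenate([x, y])).size == x.size + y.size
                  else "asymptotic")
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        stat, p = res.statistic, res.pvalue
        test = "wilcoxon"
    return TestResult(variable, test, float(stat), float(p),
                      _summary(x, norm_x), _summary(y, norm_y))


def compare_nominal(counts, *, correction: bool = False,
                    variable: str = "") -> TestResult:
    """Chi-square / Fisher routing for a 2 x k contingency table."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 2:
        raise ValueError("counts must be a 2 x k table")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError(f"{variable or 'table'}: zero margin")
    is_2x2 = counts.shape == (2, 2)
    if is_2x2 and (counts < 5).any():
        stat, p = stats.fisher_exact(counts)
        test = "fisher"
    else:
        stat, p, _, _ = stats.chi2_contingency(counts, correction=correction)
        test = "chi-square"

    def _fmt(row):
        return " | ".join(str(int(c)) for c in row)

    return TestResult(variable, test, float(stat), float(p),
                      _fmt(counts[0]), _fmt(counts[1]))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_variables(table: CohortTable, columns: list[str] | None = None,
                      alpha: float = 0.05, exclude: list[str] | None = None
                      ) -> pd.DataFrame:
    """Route every listed variable to its test; BH-adjust within this family.

    ``exclude`` names continuous columns to withhold (e.g. outlier-only
    analytes whose dichotomous recode is tested instead).
    """
    exclude = set(exclude or [])
    if columns is None:
        columns = [c for c in table.data.columns
                   if c != "group" and table.meta[c].role != "identifier"]
    rows = []
    for col in columns:
        meta = table.meta[col]
        if meta.scale == "continuous" and col in exclude:
            continue
        try:
            if meta.scale == "continuous":
                a, b = split_groups(table, col)
                res = compare_continuous(a, b, alpha, variable=col)
            else:
                counts = pd.crosstab(table.groups, table.data[col])
                counts = counts.reindex([CONTROL, GLAUCOMA]).fillna(0)
                res = compare_nominal(counts.to_numpy(), variable=col)
        except ValueError:
            continue
        rows.append(res)
    out = pd.DataFrame([vars(r) for r in rows])
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


def volcano_table(table: CohortTable, compartment: str,
                  alpha: float = 0.05, exclude: list[str] | None = None,
                  fc_threshold: float = 2.0, p_threshold: float = 1.3
                  ) -> pd.DataFrame:
    """Per-analyte log2 fold change (glaucoma/control means) vs -log10 raw p.

    Fold changes use group means of the stored concentrations; p-values are
    the *unadjusted* routed two-group p.  Labeling thresholds default to
    |log2FC| >= 2 and -log10 p >= 1.3 (p < 0.05).  A zero control mean
    flags the record undefined rather than inventing a pseudo-count.
    """
    exclude = set(exclude or [])
    rows = []
    for col in table.analyte_columns(compartment):
        if col in exclude:
            continue
        a, b = split_groups(table, col)
        if len(a) < 3 or len(b) < 3:
            continue
        res = compare_continuous(a, b, alpha, variable=col)
        mean_c, mean_g = float(np.mean(a)), float(np.mean(b))
        undefined = mean_c == 0 or mean_g == 0
        log2_fc = np.nan if undefined else float(np.log2(mean_g / mean_c))
        neg_log10_p = float(-np.log10(res.p)) if res.p > 0 else np.inf
        rows.append({
            "analyte": col, "compartment": compartment, "log2_fc": log2_fc,
            "neg_log10_p": neg_log10_p, "p": res.p, "test": res.test,
            "undefined_fc": undefined,
            "passes_fc": (not undefined) and abs(log2_fc) >= fc_threshold,
            "passes_p": neg_log10_p >= p_threshold,
            "direction": ("up" if not undefined and log2_fc > 0
                          else "down" if not undefined and log2_fc < 0 else ""),
        })
    return pd.DataFrame(rows)
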