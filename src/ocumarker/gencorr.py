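"""Outlier-tapered weighted generalized correlation analysis.

For every (dependent, independent) pair a single-predictor generalized
linear model is fitted with observation weights that taper Gaussian-fashion
outside percentile fences::

    t_low  = p10 - 1.5 (p90 - p10)        t_high = p90 + 1.5 (p90 - p10)
    w(x)   = exp(-0.5 (d / s)^2),  d = max(0, t_low - x, x - t_high),
                                   s = 0.5 (t_high - t_low)

so w = 1 inside the fences and decays smoothly outside.  Model fit is
summarized by the deviance-ratio pseudo-R^2 (McFadden convention,
``1 - residual/null deviance``) and converted to a signed correlation index

    rho = sgn(beta) sqrt(pseudo-R^2)

with effect-size bands at 0.10 (irrelevant), 0.30 (average) and 0.50
(strong).  For the linear family with unit weights rho is exactly the
Pearson correlation coefficient.

Family dispatch follows the dependent variable's scale: continuous ->
ordinary linear model; dichotomous -> quasibinomial logistic; nominal with
more than two levels -> multinomial (rho unsigned, since there is one
coefficient per level).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression

from .cohort import CohortTable, VariableMeta

FAMILIES = ("linear", "quasibinomial", "multinomial")


# --------------------------------------------------------------------------
# taper weights
# --------------------------------------------------------------------------

@dataclass
class WeightSpec:
    """Percentile fences and taper scale for the outlier down-weighting."""

    p10: float
    p90: float

    @property
    def t_low(self) -> float:
        return self.p10 - 1.5 * (self.p90 - self.p10)

    @property
    def t_high(self) -> float:
        return self.p90 + 1.5 * (self.p90 - self.p10)

    @property
    def scale(self) -> float:
        return 0.5 * (self.t_high - self.t_low)


def taper_weight(x: np.ndarray, spec: WeightSpec) -> np.ndarray:
    """Evaluate the Gaussian taper weight at x (1 inside the fences)."""
    x = np.asarray(x, dtype=float)
    if spec.scale <= 0:
        return np.where(np.isnan(x), np.nan, 1.0)
    d = np.maximum(0.0, np.maximum(spec.t_low - x, x - spec.t_high))
    return np.exp(-0.5 * (d / spec.scale) ** 2)


def robust_weights(values: np.ndarray | pd.Series) -> tuple[WeightSpec, np.ndarray]:
    """Percentile fences from the data and the per-sample weight vector.

    Requires >= 10 non-missing values.  A degenerate spread (p90 = p10)
    falls back to unit weights with a warning.  Missing values get NaN
    weights (the sample is excluded from any fit).
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[~np.isnan(arr)]
    if finite.size < 10:
        raise ValueError("need at least 10 non-missing values for percentile fences")
    p10, p90 = np.percentile(finite, [10, 90])
    spec = WeightSpec(float(p10), float(p90))
    if spec.p90 <= spec.p10:
        warnings.warn("degenerate spread (p90 = p10); using unit weights")
    return spec, taper_weight(arr, spec)


# --------------------------------------------------------------------------
# family dispatch
# --------------------------------------------------------------------------

def select_family(meta: VariableMeta, values: pd.Series | None = None) -> str:
    """Model family for a dependent variable from its declared scale."""
    if meta.scale == "continuous":
        return "linear"
    if meta.scale == "dichotomous":
        return "quasibinomial"
    if meta.scale == "nominal":
        if values is not None and pd.Series(values).dropna().nunique() <= 2:
            return "quasibinomial"
        return "multinomial"
    raise ValueError(f"undeclared scale {meta.scale!r}")


def encode_binary(values: pd.Series | np.ndarray) -> np.ndarray:
    """Map a two-level variable to 0/1 (levels in sorted order); NaN kept."""
    s = pd.Series(values)
    levels = sorted(s.dropna().unique(), key=str)
    if len(levels) > 2:
        raise ValueError(f"more than two levels: {levels}")
    mapping = {lv: float(i) for i, lv in enumerate(levels)}
    return s.map(mapping).to_numpy(dtype=float)


def pseudo_r2(resid_deviance: float, null_deviance: float) -> float:
    """Deviance-ratio pseudo-R^2, 1 - residual/null, clipped to [0, 1].

    A null deviance of 0 (no variation to explain) is defined as 0.
    """
    if not (np.isfinite(resid_deviance) and np.isfinite(null_deviance)):
        raise ValueError("deviances must be finite")
    if null_deviance == 0:
        return 0.0
    return float(np.clip(1.0 - resid_deviance / null_deviance, 0.0, 1.0))


def effect_label(rho: float) -> str:
    """Effect-size band: <=0.10 irrelevant, 0.30 average, 0.50 strong."""
    a = abs(rho)
    if a <= 0.10:
        return "irrelevant"
    if a < 0.30:
        return "weak"
    if a < 0.50:
        return "average"
    return "strong"


def correlation_index(beta: float | None, r2: float,
                      sign_defined: bool = True) -> tuple[float, str]:
    """rho = sgn(beta) sqrt(pseudo-R^2); unsigned when the sign is undefined."""
    root = float(np.sqrt(r2))
    if not sign_defined or beta is None:
        return root, effect_label(root)
    rho = float(np.sign(beta)) * root if beta != 0 else 0.0
    return rho, effect_label(rho)


# --------------------------------------------------------------------------
# the estimator
# --------------------------------------------------------------------------

class TaperWeightGLM(BaseEstimator):
    """Single-predictor weighted GLM with the tapered-outlier weights.

    Parameters
    ----------
    family : str
        ``linear``, ``quasibinomial`` or ``multinomial``.
    weighting : str
        Which margin supplies the taper weights: ``x`` (predictor),
        ``y`` (response, continuous only), ``both`` (product; the default —
        a continuous response also tapers its own outliers) or ``none``.

    Fitted attributes
    -----------------
    beta_, pvalue_, resid_deviance_, null_deviance_, pseudo_r2_, rho_,
    label_, n_, weights_, sign_defined_, converged_.
    """

    def __init__(self, family: str = "linear", weighting: str = "both"):
        self.family = family
        self.weighting = weighting

    # sklearn-style single fit; x and y are 1-D aligned vectors
    def fit(self, X, y):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        x = np.asarray(X, dtype=float).reshape(-1)
        y = pd.Series(np.asarray(y).reshape(-1))

        y_num = (y.to_numpy(dtype=float) if self.family == "linear"
                 else encode_binary(y) if self.family == "quasibinomial"
                 else pd.Series(y).astype("object").to_numpy())
        y_nan = (pd.isna(y_num) if self.family == "multinomial"
                 else np.isnan(np.asarray(y_num, dtype=float)))
        complete = ~np.isnan(x) & ~y_nan
        if complete.sum() < 10:
            raise ValueError("fewer than 10 complete pairs")

        w = np.ones(x.size)
        if self.weighting in ("x", "both"):
            _, wx = robust_weights(np.where(complete, x, np.nan))
            w = w * np.where(np.isnan(wx), 1.0, wx)
        if self.weighting in ("y", "both") and self.family == "linear":
            _, wy = robust_weights(np.where(complete, np.asarray(y_num, float), np.nan))
            w = w * np.where(np.isnan(wy), 1.0, wy)

        xc, wc = x[complete], w[complete]
        self.n_ = int(complete.sum())
        self.weights_ = wc
        self.converged_ = True
        self.sign_defined_ = self.family != "multinomial"

        if self.family == "multinomial":
            self._fit_multinomial(xc, np.asarray(y_num)[complete], wc)
        else:
            self._fit_glm(xc, np.asarray(y_num, dtype=float)[complete], wc)

        self.pseudo_r2_ = pseudo_r2(self.resid_deviance_, self.null_deviance_)
        self.rho_, self.label_ = correlation_index(
            self.beta_, self.pseudo_r2_, self.sign_defined_)
        return self

    def _fit_glm(self, x, y, w):
        fam = (sm.families.Gaussian() if self.family == "linear"
               else sm.families.Binomial())
        X = sm.add_constant(x)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.GLM(y, X, family=fam, var_weights=w)
                res = (model.fit() if self.family == "linear"
                       else model.fit(scale="X2"))  # quasi: dispersion from Pearson chi2
            self.beta_ = float(res.params[1])
            self.pvalue_ = float(res.pvalues[1])
            self.resid_deviance_ = float(res.deviance)
            self.null_deviance_ = float(res.null_deviance)
            if not np.isfinite(self.resid_deviance_):
                raise ValueError("non-finite deviance")
        except Exception:
            # perfect separation or other failure: flagged, not fatal
            self.converged_ = False
            self.beta_, self.pvalue_ = 0.0, np.nan
            self.resid_deviance_ = self.null_deviance_ = 0.0

    def _fit_multinomial(self, x, y, w):
        labels, codes = np.unique(y.astype(str), return_inverse=True)
        k = labels.size
        # null: weighted class frequencies
        freqs = np.array([w[codes == j].sum() for j in range(k)]) / w.sum()
        self.null_deviance_ = float(-2.0 * np.sum(w * np.log(freqs[codes])))
        try:
            clf = LogisticRegression(C=np.inf, max_iter=1000)
            clf.fit(x.reshape(-1, 1), codes, sample_weight=w)
            p = clf.predict_proba(x.reshape(-1, 1))
            p_obs = np.clip(p[np.arange(codes.size), codes], 1e-300, 1.0)
            self.resid_deviance_ = float(-2.0 * np.sum(w * np.log(p_obs)))
        except Exception:
            self.converged_ = False
            self.resid_deviance_ = self.null_deviance_
        self.beta_ = None
        # likelihood-ratio test, (k-1) slope parameters
        lr = max(0.0, self.null_deviance_ - self.resid_deviance_)
        self.pvalue_ = float(stats.chi2.sf(lr, df=max(k - 1, 1)))


def fit_weighted_model(y, x, family: str = "linear",
                       weighting: str = "both") -> TaperWeightGLM:
    """Functional wrapper over :class:`TaperWeightGLM` (note the y-first order)."""
    return TaperWeightGLM(family=family, weighting=weighting).fit(x, y)


# --------------------------------------------------------------------------
# screening orchestration
# --------------------------------------------------------------------------

def correlation_screen(table: CohortTable, dependents: list[str],
                       independents: list[str], weighting: bool = True,
                       min_n: int = 10) -> pd.DataFrame:
    """One CorrelationRecord per (dependent, independent) pair.

    Pairs with fewer than ``min_n`` pairwise-complete samples are skipped
    (reported with NaN statistics and the reason).  p-values are BH-adjusted
    within the screen.
    """
    from .grouptests import bh_adjust

    records = []
    mode = "both" if weighting else "none"
    for dep in dependents:
        meta = table.meta[dep]
        fam = select_family(meta, table.data[dep])
        for ind in independents:
            if ind == dep:
                continue
            rec = {"dependent": dep, "independent": ind, "family": fam,
                   "rho": np.nan, "pseudo_r2": np.nan, "p": np.nan,
                   "p_adj": np.nan, "n": 0, "label": "", "flag": ""}
            ind_meta = table.meta[ind]
            if ind_meta.scale == "nominal":
                rec["flag"] = "skipped_nominal_independent"
                records.append(rec)
                continue
            x = (encode_binary(table.data[ind]) if ind_meta.scale == "dichotomous"
                 else pd.to_numeric(table.data[ind], errors="coerce").to_numpy())
            y = table.data[dep]
            complete = ~np.isnan(x) & y.notna().to_numpy()
            if complete.sum() < min_n:
                rec["flag"] = "skipped_insufficient_n"
                records.append(rec)
                continue
            fit = TaperWeightGLM(family=fam, weighting=mode).fit(x, y)
            rec.update(rho=fit.rho_, pseudo_r2=fit.pseudo_r2_, p=fit.pvalue_,
                       n=fit.n_, label=fit.label_)
            if not fit.converged_:
                rec["flag"] = "non_converged"
            elif not fit.sign_defined_:
                rec["flag"] = "sign_undefined"
            records.append(rec)
    out = pd.DataFrame.from_records(records)
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "p_adj"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out
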