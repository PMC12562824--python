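"""Five-step multivariable biomarker selection.

1.  Variable filtering: drop constants, variables with under 66%
    completeness, and categorical variables with any level held by fewer
    than seven samples.
2.  Chained-equations imputation where each target variable is predicted by
    exactly one representative per predictor cluster; clusters come from
    agglomerative clustering of the pairwise pseudo-R^2 matrix cut at
    k = max(3, ceil((p - 50)/8)) for p candidate variables.
3.  Stability selection: 100 runs of 5-fold cross-validated Lasso; variables
    selected in fewer than 5% of runs are discarded; a concluding Lasso at
    the median cross-validated penalty picks the working set, relaxed along
    the path until the permissive size bound n >= 35 + 6.5 m holds.
4.  Backward reduction of the unpenalized refit (largest Wald p dropped
    first) until the strict bound n >= 50 + 8 m holds.
5.  Refit on the original, non-imputed data (complete cases for the model's
    variables), again reducing until the strict bound holds at that n.

The emitted model reports residual and null deviance, the deviance-ratio
pseudo-R^2, and per-variable coefficient signs from the final refit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from sklearn.cluster import AgglomerativeClustering
from sklearn.linear_model import Lasso, LassoCV, LinearRegression, LogisticRegression
from sklearn.model_selection import KFold

from .cohort import CohortTable
from .gencorr import pseudo_r2


@dataclass
class MVAConfig:
    dependent: str
    candidates: list[str] | None = None
    runs: int = 100
    folds: int = 5
    retention_threshold: float = 0.05
    completeness_threshold: float = 0.66
    min_per_category: int = 7
    lasso_bound: tuple[float, float] = (35.0, 6.5)   # n >= a + b*m at Lasso stage
    final_bound: tuple[float, float] = (50.0, 8.0)   # n >= a + b*m at final stage
    seed: int = 0

    def validate(self) -> None:
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        for name in ("retention_threshold", "completeness_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1)")


def max_model_size(n: int, bound: tuple[float, float]) -> int:
    """Largest m with n >= a + b*m (never below 0)."""
    a, b = bound
    return max(0, int(math.floor((n - a) / b)))


def retained_from_frequencies(frequencies: pd.Series, threshold: float = 0.05
                              ) -> list[str]:
    """Variables kept by the retention rule: frequency >= threshold.

    "Selected in fewer than 5% of runs" discards, so exactly 5 of 100 runs
    survives while 4 of 100 does not.
    """
    return list(frequencies.index[frequencies >= threshold])


@dataclass
class StabilityResult:
    frequencies: pd.Series          # per-variable selection frequency
    alphas: list[float]             # per-run CV-optimal penalty
    median_alpha: float
    retained: list[str]


@dataclass
class MVAModel:
    dependent: str
    variables: list[str]
    signs: dict[str, str]           # variable -> "+" | "-"
    coefs: dict[str, float]
    n: int
    resid_deviance: float
    null_deviance: float
    pseudo_r2: float
    stage: str = "original"
    warnings: list[str] = field(default_factory=list)
    audit: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# step 1: variable filtering
# --------------------------------------------------------------------------

def filter_variables(table: CohortTable, config: MVAConfig
                     ) -> tuple[list[str], dict[str, str]]:
    """Drop constants, low-completeness and thin-category candidates."""
    candidates = config.candidates
    if candidates is None:
        candidates = [c for c in table.data.columns
                      if c != "group" and c != config.dependent
                      and table.meta[c].role != "identifier"]
    n = table.n_samples
    kept, dropped = [], {}
    for col in candidates:
        vals = table.data[col]
        obs = vals.dropna()
        if obs.nunique() <= 1:
            dropped[col] = "constant"
            continue
        if len(obs) / n < config.completeness_threshold:
            dropped[col] = "completeness_below_threshold"
            continue
        if table.meta[col].scale in ("dichotomous", "nominal"):
            if obs.value_counts().min() < config.min_per_category:
                dropped[col] = "category_below_min_count"
                continue
        kept.append(col)
    dep = table.data[config.dependent].dropna()
    if dep.nunique() <= 1 or len(dep) / n < config.completeness_threshold:
        raise ValueError(f"dependent variable {config.dependent!r} fails the filter")
    return kept, dropped


# --------------------------------------------------------------------------
# numeric encoding (nominal -> reference-dropped dummies)
# --------------------------------------------------------------------------

def encode_design(table: CohortTable, variables: list[str]
                  ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Numeric design frame; returns (frame, variable -> encoded columns)."""
    cols: dict[str, list[str]] = {}
    parts = []
    for col in variables:
        meta = table.meta[col]
        s = table.data[col]
        if meta.scale == "continuous":
            parts.append(pd.to_numeric(s, errors="coerce").rename(col))
            cols[col] = [col]
        elif meta.scale == "dichotomous":
            levels = sorted(s.dropna().unique(), key=str)
            enc = s.map({lv: float(i) for i, lv in enumerate(levels)})
            parts.append(enc.astype(float).rename(col))
            cols[col] = [col]
        else:
            d = pd.get_dummies(s, prefix=col, dtype=float)
            d[s.isna()] = np.nan
            d = d.iloc[:, 1:]  # reference level dropped
            parts.append(d)
            cols[col] = list(d.columns)
    frame = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=table.data.index)
    return frame, cols


# --------------------------------------------------------------------------
# step 2a: predictor clustering on the pairwise pseudo-R^2 matrix
# --------------------------------------------------------------------------

def _pairwise_r2(X: pd.DataFrame, binary: set[str]) -> pd.DataFrame:
    """Symmetrized single-predictor pseudo-R^2 between encoded columns.

    Continuous targets use the linear closed form (squared Pearson on
    pairwise-complete rows, identical to the single-predictor linear
    deviance ratio).  Binary targets use the logistic deviance ratio.
    The matrix is symmetrized with max(R2(i~j), R2(j~i)).
    """
    cols = list(X.columns)
    r2 = X.corr(min_periods=4) ** 2  # linear-family closed form
    r2 = r2.fillna(0.0)
    for i in cols:
        if i not in binary:
            continue
        yi = X[i]
        for j in cols:
            if i == j:
                continue
            pair = pd.concat([yi, X[j]], axis=1).dropna()
            if len(pair) < 10 or pair[i].nunique() < 2:
                continue
            y = pair[i].to_numpy()
            x = pair[j].to_numpy().reshape(-1, 1)
            p1 = y.mean()
            null_dev = -2.0 * (y.sum() * np.log(p1) + (len(y) - y.sum()) * np.log(1 - p1))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    clf = LogisticRegression(C=np.inf, max_iter=200)
                    clf.fit(x, y)
                    p = np.clip(clf.predict_proba(x)[:, 1], 1e-12, 1 - 1e-12)
                dev = -2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
                r2.loc[i, j] = pseudo_r2(dev, null_dev)
            except Exception:
                pass
    sym = np.maximum(r2.to_numpy(), r2.to_numpy().T)
    np.fill_diagonal(sym, 1.0)
    return pd.DataFrame(np.clip(sym, 0.0, 1.0), index=cols, columns=cols)


def cluster_predictors(X: pd.DataFrame, binary: set[str] | None = None
                       ) -> tuple[pd.Series, int]:
    """Agglomerative clustering of predictors at distance 1 - pseudo-R^2.

    k = max(3, ceil((p - 50)/8)) clusters for p predictors; with fewer than
    3 predictors each is its own cluster.
    """
    cols = list(X.columns)
    p = len(cols)
    if p < 3:
        return pd.Series(range(p), index=cols), p
    k = max(3, math.ceil((p - 50) / 8))
    k = min(k, p)
    dist = 1.0 - _pairwise_r2(X, binary or set()).to_numpy()
    np.fill_diagonal(dist, 0.0)
    model = AgglomerativeClustering(n_clusters=k, metric="precomputed",
                                    linkage="average")
    labels = model.fit_predict(dist)
    return pd.Series(labels, index=cols), k


def cluster_representatives(X: pd.DataFrame, labels: pd.Series,
                            binary: set[str] | None = None) -> dict[int, str]:
    """Medoid of each cluster: smallest mean distance to its own members."""
    dist = 1.0 - _pairwise_r2(X, binary or set())
    reps = {}
    for lab in sorted(labels.unique()):
        members = labels.index[labels == lab]
        sub = dist.loc[members, members]
        reps[int(lab)] = str(sub.mean(axis=1).idxmin())
    return reps


# --------------------------------------------------------------------------
# step 2b: chained-equations imputation with cluster-representative predictors
# --------------------------------------------------------------------------

def impute_chained(X: pd.DataFrame, labels: pd.Series, seed: int,
                   binary: set[str] | None = None, cycles: int = 10,
                   pmm_donors: int = 5) -> pd.DataFrame:
    """Single-dataset chained-equations imputation.

    Continuous targets use predictive mean matching (nearest ``pmm_donors``
    observed predictions, one drawn at random); binary targets a logistic
    draw.  Each target's predictor set is the cluster representatives
    (excluding the target itself).  Observed cells are never altered;
    variables over 95% missing are left mean/mode-filled with a warning.
    """
    binary = binary or set()
    rng = np.random.default_rng(seed)
    out = X.copy().astype(float)
    miss = {c: out[c].isna().to_numpy() for c in out.columns}
    if not any(m.any() for m in miss.values()):
        return out

    # initial fill: mean (continuous) / mode (binary)
    for c in out.columns:
        if miss[c].any():
            fill = out[c].mode().iloc[0] if c in binary else out[c].mean()
            out.loc[miss[c], c] = fill

    reps = cluster_representatives(X, labels, binary)
    skip = set()
    for c in out.columns:
        if miss[c].mean() > 0.95:
            warnings.warn(f"{c}: >95% missing, excluded from chained imputation")
            skip.add(c)

    targets = [c for c in out.columns if miss[c].any() and c not in skip]
    for _ in range(cycles):
        for c in targets:
            preds = [r for r in reps.values() if r != c]
            if not preds:
                continue
            Z = out[preds].to_numpy()
            obs = ~miss[c]
            y_obs = out.loc[obs, c].to_numpy()
            try:
                if c in binary and len(np.unique(y_obs)) == 2:
                    clf = LogisticRegression(max_iter=200)
                    clf.fit(Z[obs], y_obs.astype(int))
                    p = clf.predict_proba(Z[miss[c]])[:, 1]
                    out.loc[miss[c], c] = (rng.random(p.size) < p).astype(float)
                else:
                    reg = LinearRegression().fit(Z[obs], y_obs)
                    pred_obs = reg.predict(Z[obs])
                    pred_mis = reg.predict(Z[miss[c]])
                    # predictive mean matching
                    order = np.argsort(pred_obs)
                    sorted_pred, sorted_y = pred_obs[order], y_obs[order]
                    idx = np.searchsorted(sorted_pred, pred_mis)
                    draws = np.empty(pred_mis.size)
                    for t, i in enumerate(idx):
                        lo, hi = max(0, i - pmm_donors), min(sorted_y.size, i + pmm_donors)
                        pool = sorted_y[lo:hi]
                        draws[t] = pool[rng.integers(pool.size)]
                    out.loc[miss[c], c] = draws
            except Exception:
                continue
    return out


# --------------------------------------------------------------------------
# step 3: stability selection
# --------------------------------------------------------------------------

class StabilityLassoSelector(BaseEstimator):
    """Repeated cross-validated Lasso stability selection (linear response).

    Each of ``runs`` repetitions re-randomizes a ``folds``-fold split,
    picks the CV-optimal penalty on the full Lasso path and records the
    nonzero set of the path fit at that penalty.  Variables selected in
    fewer than ``retention_threshold`` of runs are discarded.

    Fitted attributes: ``frequencies_`` (per-column selection frequency),
    ``alphas_`` (per-run optima), ``median_alpha_``, ``support_``,
    ``retained_`` (column names when fit on a DataFrame).
    """

    def __init__(self, runs: int = 100, folds: int = 5,
                 retention_threshold: float = 0.05, lambda_rule: str = "1se",
                 random_state: int = 0):
        self.runs = runs
        self.folds = folds
        self.retention_threshold = retention_threshold
        self.lambda_rule = lambda_rule
        self.random_state = random_state

    def fit(self, X, y):
        if self.lambda_rule not in ("1se", "min"):
            raise ValueError("lambda_rule must be '1se' or 'min'")
        columns = list(X.columns) if isinstance(X, pd.DataFrame) else None
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.shape[0] < self.folds:
            raise ValueError("n must be at least the number of folds")
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        Xs = (X - mu) / sd

        ss = np.random.SeedSequence(self.random_state)
        seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(self.runs)]
        counts = np.zeros(X.shape[1])
        alphas = []
        for seed in seeds:
            kf = KFold(n_splits=self.folds, shuffle=True, random_state=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cv = LassoCV(cv=kf, alphas=100, max_iter=5000).fit(Xs, y)
                alpha = float(cv.alpha_)
                if self.lambda_rule == "1se":
                    # largest penalty within one SE of the CV minimum
                    mean_mse = cv.mse_path_.mean(axis=1)
                    se = cv.mse_path_.std(axis=1, ddof=1) / np.sqrt(self.folds)
                    i_min = int(np.argmin(mean_mse))
                    ok = mean_mse <= mean_mse[i_min] + se[i_min]
                    alpha = float(cv.alphas_[ok].max())
                    coef = Lasso(alpha=alpha, max_iter=5000).fit(Xs, y).coef_
                else:
                    coef = cv.coef_
            alphas.append(alpha)
            counts += coef != 0
        self.frequencies_ = pd.Series(counts / self.runs,
                                      index=columns if columns else range(X.shape[1]))
        self.alphas_ = alphas
        self.median_alpha_ = float(np.median(alphas))
        self.retained_ = retained_from_frequencies(self.frequencies_,
                                                   self.retention_threshold)
        self.support_ = self.frequencies_.index.isin(self.retained_)
        if not self.support_.any():
            warnings.warn("stability selection retained no variables")
        return self

    def get_support(self):
        return self.support_


def stability_lasso(y, X: pd.DataFrame, config: MVAConfig) -> StabilityResult:
    """Functional wrapper over :class:`StabilityLassoSelector`."""
    sel = StabilityLassoSelector(runs=config.runs, folds=config.folds,
                                 retention_threshold=config.retention_threshold,
                                 random_state=config.seed).fit(X, y)
    return StabilityResult(frequencies=sel.frequencies_, alphas=sel.alphas_,
                           median_alpha=sel.median_alpha_, retained=sel.retained_)


# --------------------------------------------------------------------------
# steps 3b-5: concluding Lasso, backward reduction, refit on original data
# --------------------------------------------------------------------------

def _ols_fit(y: np.ndarray, X: np.ndarray):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def _lasso_select(Xs: np.ndarray, y: np.ndarray, alpha: float,
                  limit: int) -> tuple[np.ndarray, float]:
    """Nonzero set of the Lasso at alpha, raising alpha until |set| <= limit."""
    a = alpha
    for _ in range(200):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coef = Lasso(alpha=a, max_iter=5000).fit(Xs, y).coef_
        sel = coef != 0
        if sel.sum() <= limit:
            return sel, a
        a *= 1.1
    return sel, a


def final_fit_and_reduce(y: pd.Series, X_imputed: pd.DataFrame,
                         X_original: pd.DataFrame, median_alpha: float,
                         config: MVAConfig) -> MVAModel:
    """Concluding Lasso + size-bounded backward reduction + original-data refit."""
    audit: dict = {"median_alpha": median_alpha, "backward_steps": []}
    notes: list[str] = []
    yv = np.asarray(y, dtype=float)
    n = yv.size

    cols = list(X_imputed.columns)
    Xi = X_imputed.to_numpy(dtype=float)
    mu, sd = Xi.mean(axis=0), Xi.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (Xi - mu) / sd

    # (a) concluding Lasso at the median penalty, relaxed to the permissive bound
    limit = max_model_size(n, config.lasso_bound)
    sel, used_alpha = _lasso_select(Xs, yv - yv.mean(), median_alpha, limit)
    current = [c for c, s in zip(cols, sel) if s]
    audit["concluding_alpha"] = used_alpha
    audit["lasso_selected"] = list(current)

    # (b) unpenalized refit on imputed data; reduce to the strict bound
    limit_final = max_model_size(n, config.final_bound)
    while current:
        res = _ols_fit(yv, X_imputed[current].to_numpy())
        if len(current) <= limit_final:
            break
        pv = pd.Series(res.pvalues[1:], index=current)
        worst = str(pv.idxmax())
        audit["backward_steps"].append({"stage": "imputed", "dropped": worst,
                                        "p": float(pv.max())})
        current.remove(worst)

    # (c) refit on original, non-imputed data (complete cases), reduce again
    while True:
        frame = pd.concat([pd.Series(yv, index=X_original.index, name="__y__"),
                           X_original[current]], axis=1).dropna()
        n_cc = len(frame)
        if not current:
            res = _ols_fit(frame["__y__"].to_numpy(), np.empty((n_cc, 0)))
            break
        res = _ols_fit(frame["__y__"].to_numpy(), frame[current].to_numpy())
        if len(current) <= max_model_size(n_cc, config.final_bound):
            break
        pv = pd.Series(res.pvalues[1:], index=current)
        worst = str(pv.idxmax())
        audit["backward_steps"].append({"stage": "original", "dropped": worst,
                                        "p": float(pv.max())})
        current.remove(worst)

    if n_cc < config.final_bound[0] + config.final_bound[1]:
        notes.append("complete_case_n_below_minimum")

    resid_dev = float(res.ssr) if current else float(((frame["__y__"] - frame["__y__"].mean()) ** 2).sum())
    null_dev = float(((frame["__y__"] - frame["__y__"].mean()) ** 2).sum())
    coefs = ({c: float(b) for c, b in zip(current, res.params[1:])} if current else {})
    return MVAModel(
        dependent=str(y.name) if y.name else "", variables=list(current),
        signs={c: ("+" if b > 0 else "-") for c, b in coefs.items()},
        coefs=coefs, n=n_cc, resid_deviance=resid_dev, null_deviance=null_dev,
        pseudo_r2=pseudo_r2(resid_dev, null_dev), stage="original",
        warnings=notes, audit=audit)


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------

def run_mva(table: CohortTable, dependent: str, config: MVAConfig | None = None
            ) -> MVAModel:
    """Execute filter -> cluster -> impute -> stability -> reduce/refit."""
    if config is None:
        config = MVAConfig(dependent=dependent)
    config.dependent = dependent
    config.validate()

    kept, dropped = filter_variables(table, config)
    audit: dict = {"filtered_out": dropped, "candidates": list(kept)}

    # rows with an observed dependent only
    y_all = pd.to_numeric(table.data[dependent], errors="coerce")
    rows = y_all.notna()
    X_orig, enc_map = encode_design(table, kept)
    X_orig = X_orig.loc[rows]
    y = y_all.loc[rows].rename(dependent)

    binary = {c for v, cs in enc_map.items() for c in cs
              if table.meta[v].scale in ("dichotomous", "nominal")}
    labels, k = cluster_predictors(X_orig, binary)
    audit["n_clusters"] = k

    ss = np.random.SeedSequence(config.seed)
    seed_impute, seed_stab = (int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(2))
    X_imp = impute_chained(X_orig, labels, seed_impute, binary)

    stab_cfg = MVAConfig(**{**vars(config), "seed": seed_stab})
    stab = stability_lasso(y.to_numpy(), X_imp, stab_cfg)
    audit["selection_frequencies"] = stab.frequencies.to_dict()
    audit["median_alpha"] = stab.median_alpha
    audit["stability_retained"] = list(stab.retained)

    if not stab.retained:
        model = MVAModel(dependent=dependent, variables=[], signs={}, coefs={},
                         n=int(rows.sum()), resid_deviance=np.nan,
                         null_deviance=np.nan, pseudo_r2=0.0,
                         warnings=["empty_stability_retention"], audit=audit)
        return model

    model = final_fit_and_reduce(y, X_imp[stab.retained], X_orig[stab.retained],
                                 stab.median_alpha, config)
    model.dependent = dependent
    model.audit = {**audit, **model.audit}
    return model
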