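"""Multivariable procedure: filter rules, cluster count formula, imputation
contracts, stability retention, size bounds and backward-reduction
monotonicity."""

import warnings

import numpy as np
import pandas as pd
import pytest

import ocumarker as om
from conftest import small_table
from ocumarker.mva import (cluster_predictors, cluster_representatives,
                           encode_design, impute_chained)


def _rng(seed=0):
    return np.random.default_rng(seed)


# --------------------------------------------------------------------------
# step 1: filtering
# --------------------------------------------------------------------------

class TestFilter:
    def _table(self):
        rng = _rng(1)
        n = 117
        cols = {
            "dep": rng.normal(size=n),
            "ok": rng.normal(size=n),
            "constant": np.full(n, 2.0),
            "sparse": np.where(rng.random(n) < 0.45, np.nan, rng.normal(size=n)),
            "thin_cat": np.array([1.0] * 6 + [0.0] * (n - 6)),
        }
        t = small_table(cols, scales={"thin_cat": "dichotomous"}, n_control=30)
        t.meta["dep"].role = "dependent-candidate"
        return t

    def test_rules(self):
        t = self._table()
        kept, dropped = om.filter_variables(t, om.MVAConfig(dependent="dep"))
        assert "ok" in kept
        assert dropped["constant"] == "constant"
        assert dropped["sparse"] == "completeness_below_threshold"
        assert dropped["thin_cat"] == "category_below_min_count"

    def test_sixty_percent_complete_is_dropped(self):
        rng = _rng(2)
        n = 100
        vals = rng.normal(size=n)
        vals[:40] = np.nan   # 60% complete < 66%
        t = small_table({"dep": rng.normal(size=n), "v": vals}, n_control=30)
        _, dropped = om.filter_variables(t, om.MVAConfig(dependent="dep"))
        assert dropped["v"] == "completeness_below_threshold"

    def test_filtered_dependent_aborts(self):
        t = self._table()
        with pytest.raises(ValueError, match="constant"):
            om.run_mva(t, "constant")


# --------------------------------------------------------------------------
# step 2: clustering and imputation
# --------------------------------------------------------------------------

class TestClustering:
    def test_k_formula(self):
        rng = _rng(3)
        X40 = pd.DataFrame(rng.normal(size=(60, 40)))
        X40.columns = [f"v{i}" for i in range(40)]
        _, k = cluster_predictors(X40)
        assert k == 3                      # max(3, ceil(-10/8)) -> 3
        X114 = pd.DataFrame(rng.normal(size=(60, 114)),
                            columns=[f"v{i}" for i in range(114)])
        _, k = cluster_predictors(X114)
        assert k == 8                      # ceil(64/8)

    def test_duplicated_variables_share_a_cluster(self):
        rng = _rng(4)
        base = rng.normal(size=80)
        cols = {f"v{i}": rng.normal(size=80) for i in range(8)}
        cols["dup1"] = base
        cols["dup2"] = base.copy()
        labels, _ = cluster_predictors(pd.DataFrame(cols))
        assert labels["dup1"] == labels["dup2"]

    def test_tiny_panels_get_singleton_clusters(self):
        X = pd.DataFrame(_rng(5).normal(size=(30, 2)), columns=["a", "b"])
        labels, k = cluster_predictors(X)
        assert k == 2 and labels.nunique() == 2


class TestImputation:
    def _frame(self, seed=6, n=150):
        rng = _rng(seed)
        a = rng.normal(size=n)
        b = 0.8 * a + 0.6 * rng.normal(size=n)   # r = 0.8 with its cluster mate
        c = rng.normal(size=n)
        return pd.DataFrame({"a": a, "b": b, "c": c})

    def test_complete_frame_unchanged(self):
        X = self._frame()
        labels, _ = cluster_predictors(X)
        out = impute_chained(X, labels, seed=1)
        pd.testing.assert_frame_equal(out, X)

    def test_observed_cells_never_altered(self):
        X = self._frame()
        miss = _rng(7).random(len(X)) < 0.2
        Xm = X.copy()
        Xm.loc[miss, "b"] = np.nan
        labels, _ = cluster_predictors(Xm)
        out = impute_chained(Xm, labels, seed=2)
        pd.testing.assert_series_equal(out.loc[~miss, "b"], X.loc[~miss, "b"])
        assert out["b"].notna().all()

    def test_beats_mean_imputation_on_correlated_variable(self):
        X = self._frame(seed=8, n=400)
        miss = _rng(9).random(len(X)) < 0.10
        Xm = X.copy()
        Xm.loc[miss, "b"] = np.nan
        labels, _ = cluster_predictors(Xm)
        out = impute_chained(Xm, labels, seed=3)
        rmse = np.sqrt(((out.loc[miss, "b"] - X.loc[miss, "b"]) ** 2).mean())
        rmse_mean = np.sqrt(((Xm["b"].mean() - X.loc[miss, "b"]) ** 2).mean())
        assert rmse < rmse_mean


# --------------------------------------------------------------------------
# step 3: stability selection
# --------------------------------------------------------------------------

class TestStability:
    def test_retention_boundary(self):
        freq = pd.Series({"four": 0.04, "five": 0.05, "many": 0.80})
        assert om.retained_from_frequencies(freq) == ["five", "many"]

    def test_planted_predictor_selected_nearly_always(self):
        rng = _rng(10)
        n = 150
        X = pd.DataFrame(rng.normal(size=(n, 21)),
                         columns=[f"x{i}" for i in range(21)])
        y = 0.8 * X["x0"] + 0.6 * rng.normal(size=n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = om.StabilityLassoSelector(random_state=0).fit(X, y)
        assert sel.frequencies_["x0"] >= 0.95
        assert "x0" in sel.retained_
        assert np.isfinite(sel.median_alpha_)

    def test_frequencies_invariant_to_column_order(self):
        rng = _rng(11)
        n = 120
        X = pd.DataFrame(rng.normal(size=(n, 6)), columns=list("abcdef"))
        y = 0.7 * X["a"] - 0.5 * X["d"] + rng.normal(size=n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1 = om.StabilityLassoSelector(runs=25, random_state=3).fit(X, y).frequencies_
            f2 = om.StabilityLassoSelector(runs=25, random_state=3).fit(
                X[list("fedcba")], y).frequencies_
        pd.testing.assert_series_equal(f1.sort_index(), f2.sort_index())


# --------------------------------------------------------------------------
# steps 4-5: size bounds, reduction, refit
# --------------------------------------------------------------------------

class TestSizeBounds:
    def test_bounds_at_study_n(self):
        assert om.max_model_size(87, (35.0, 6.5)) == 8    # 87 = 35 + 6.5*8 exactly
        assert om.max_model_size(87, (50.0, 8.0)) == 4    # fails at m = 5
        assert om.max_model_size(117, (50.0, 8.0)) == 8

    def test_reduction_is_noop_when_bounds_hold(self):
        rng = _rng(12)
        n = 117
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        y = (X["a"] - X["b"] + 0.3 * rng.normal(size=n)).rename("y")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = om.final_fit_and_reduce(y, X, X, median_alpha=0.01,
                                        config=om.MVAConfig(dependent="y"))
        assert set(m.variables) <= {"a", "b", "c"}
        assert {"a", "b"} <= set(m.variables)
        assert m.signs["a"] == "+" and m.signs["b"] == "-"
        assert m.audit["backward_steps"] == []

    def test_final_model_respects_strict_bound(self):
        rng = _rng(13)
        n = 60                              # strict bound allows m <= 1
        X = pd.DataFrame(rng.normal(size=(n, 10)),
                         columns=[f"x{i}" for i in range(10)])
        y = (X @ np.linspace(1, 0.5, 10) + rng.normal(size=n)).rename("y")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = om.final_fit_and_reduce(y, X, X, median_alpha=1e-3,
                                        config=om.MVAConfig(dependent="y"))
        assert len(m.variables) <= om.max_model_size(n, (50.0, 8.0))
        # reduction is monotone: each audit step drops exactly one variable
        dropped = [s["dropped"] for s in m.audit["backward_steps"]]
        assert len(dropped) == len(set(dropped))


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------

def _planted_cohort(seed):
    """n = 117, one driver (standardized coefficient 0.6) + 30 noise analytes."""
    from ocumarker.cohort import CONTROL, GLAUCOMA
    analytes = [om.AnalyteSpec(f"N{i}", "AqH", 3.0, 0.5) for i in range(30)]
    analytes.append(om.AnalyteSpec("Driver", "AqH", 3.0, 0.5))
    var = om.VariableSpec("T", role="dependent-candidate",
                          mean={CONTROL: 40.0, GLAUCOMA: 40.0},
                          sd={CONTROL: 5.0, GLAUCOMA: 5.0})
    cfg = om.SyntheticConfig(n_control=30, n_glaucoma=87, analytes=analytes,
                             variables=[var],
                             couplings=[om.CouplingSpec("Driver_AqH", "T", 0.6)],
                             seed=seed)
    return om.generate_cohort(cfg)[0]


def test_run_mva_recovers_planted_driver_and_is_deterministic():
    table = _planted_cohort(19)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m1 = om.run_mva(table, "T", om.MVAConfig(dependent="T", seed=5))
        m2 = om.run_mva(table, "T", om.MVAConfig(dependent="T", seed=5))
    assert "Driver_AqH" in m1.variables
    assert m1.signs["Driver_AqH"] == "+"
    assert m1.variables == m2.variables
    assert m1.coefs == m2.coefs
    assert len(m1.variables) <= om.max_model_size(m1.n, (50.0, 8.0))


def test_run_mva_on_null_cohort_stays_small():
    """With nothing planted the final model rarely exceeds one variable."""
    from ocumarker.cohort import CONTROL, GLAUCOMA
    small = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in range(10):
            analytes = [om.AnalyteSpec(f"N{i}", "AqH", 3.0, 0.5) for i in range(20)]
            var = om.VariableSpec("T", role="dependent-candidate",
                                  mean={CONTROL: 40.0, GLAUCOMA: 40.0},
                                  sd={CONTROL: 5.0, GLAUCOMA: 5.0})
            cfg = om.SyntheticConfig(n_control=30, n_glaucoma=87,
                                     analytes=analytes, variables=[var], seed=seed)
            table, _ = om.generate_cohort(cfg)
            m = om.run_mva(table, "T", om.MVAConfig(dependent="T", seed=seed))
            small += len(m.variables) <= 1
    assert small >= 8


def test_run_mva_with_missingness_still_respects_contracts():
    from ocumarker.cohort import CONTROL, GLAUCOMA
    table = _planted_cohort(23)
    # knock out 10% of analyte cells
    rng = _rng(24)
    for col in table.analyte_columns():
        hit = rng.random(table.n_samples) < 0.10
        table.data.loc[hit, col] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = om.run_mva(table, "T", om.MVAConfig(dependent="T", seed=6))
    assert len(m.variables) <= om.max_model_size(m.n, (50.0, 8.0))
    assert m.pseudo_r2 == pytest.approx(
        1 - m.resid_deviance / m.null_deviance, abs=1e-9)
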