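"""Group tests, logistic fit, stepwise selection, calibration and ROC."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from ocuflow import (CohortTable, StepwiseLogisticScreener, chi_square_2x2,
                     compare_groups, fit_logistic, format_report,
                     hosmer_lemeshow, model_comparison_report, nagelkerke_r2,
                     replay_trace, roc_analysis, stepwise_wald)
from ocuflow.screening import _expit, _score_test, _stepwise_core
from ocuflow.synthetic import CohortSimConfig, VariableSpec, simulate_cohort
from ocuflow.tables import GROUP_CASE, GROUP_CONTROL


def _table(ctrl, case, name="x", kind="continuous"):
    df = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(len(ctrl) + len(case))],
        "group": [GROUP_CONTROL] * len(ctrl) + [GROUP_CASE] * len(case),
        name: np.concatenate([ctrl, case]),
    })
    t = CohortTable(df)
    t.variables[name].kind = kind
    return t


# ----------------------------------------------------------------- chi-square
def test_gender_table_chi_square():
    res = chi_square_2x2(45, 21, 52, 14)
    assert res.statistic == pytest.approx(1.91, abs=0.005)
    assert res.p_value == pytest.approx(0.168, abs=5e-4)


def test_independent_table_chi_square_zero():
    res = chi_square_2x2(10, 10, 10, 10)
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_zero_margin_rejected():
    with pytest.raises(ValueError, match="margin"):
        chi_square_2x2(0, 0, 5, 5)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.tuples(*[st.integers(min_value=1, max_value=60)] * 4))
def test_chi_square_matches_brute_force_oracle(counts):
    a, b, c, d = counts
    res = chi_square_2x2(a, b, c, d)
    n = a + b + c + d
    exp = [[(a + b) * (a + c) / n, (a + b) * (b + d) / n],
           [(c + d) * (a + c) / n, (c + d) * (b + d) / n]]
    obs = [[a, b], [c, d]]
    brute = sum((obs[i][j] - exp[i][j]) ** 2 / exp[i][j]
                for i in range(2) for j in range(2))
    assert res.statistic == pytest.approx(brute, abs=1e-10)


# ------------------------------------------------------------- group compare
def test_identical_samples_not_significant(rng):
    x = rng.standard_normal(40)
    res = compare_groups(_table(x, x), "x")
    assert res.test_name == "t-test"
    assert res.p_value >= 0.99


def test_lognormal_variable_takes_rank_branch(rng):
    res = compare_groups(
        _table(rng.lognormal(0, 1, 60), rng.lognormal(0.2, 1, 60)), "x")
    assert res.test_name == "Mann-Whitney"
    assert "median_control" in res.extra and "mean_rank_case" in res.extra


def test_binary_variable_delegates_to_chi_square(rng):
    ctrl = (rng.random(66) < 45 / 66).astype(float)
    case = (rng.random(66) < 52 / 66).astype(float)
    res = compare_groups(_table(ctrl, case, kind="binary"), "x")
    assert res.test_name == "chi-square"


def test_vs_power_at_published_effect_size(rng):
    # Table-style effect: 0.38+/-0.04 vs 0.35+/-0.04, n=66/66
    hits = 0
    for _ in range(200):
        res = compare_groups(_table(rng.normal(0.38, 0.04, 66),
                                    rng.normal(0.35, 0.04, 66)), "x")
        hits += res.p_value < 0.05
    assert hits >= 180


def test_small_group_rejected(rng):
    with pytest.raises(ValueError, match=">= 3"):
        compare_groups(_table(rng.normal(size=2), rng.normal(size=30)), "x")


# ----------------------------------------------------------------- logistic
def test_logistic_matches_statsmodels(rng):
    x = rng.normal(size=(800, 3))
    y = (rng.random(800) < _expit(-0.5 + x @ [0.8, -0.4, 0.0])).astype(float)
    fit = fit_logistic(y, x)
    ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
    np.testing.assert_allclose(fit.coefficients, ref.params, rtol=1e-6)
    np.testing.assert_allclose(fit.standard_errors, ref.bse, rtol=1e-5)
    assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-6)
    assert fit.converged and not fit.separation


def test_logistic_gradient_norm_small_at_optimum(rng):
    x = rng.normal(size=(500, 2))
    y = (rng.random(500) < _expit(0.3 + x @ [1.0, -1.0])).astype(float)
    fit = fit_logistic(y, x)
    A = np.column_stack([np.ones(500), x])
    grad = A.T @ (y - fit.fitted_probabilities)
    assert np.linalg.norm(grad) < 1e-6


def test_null_slope_within_2se(rng):
    x = rng.normal(size=5000)
    y = (rng.random(5000) < 0.4).astype(float)
    fit = fit_logistic(y, x[:, None])
    assert abs(fit.coefficients[1]) < 2 * fit.standard_errors[1]


def test_parameter_recovery_within_2se(rng):
    x = rng.normal(size=2000)
    y = (rng.random(2000) < _expit(-1.0 + 0.8 * x)).astype(float)
    fit = fit_logistic(y, x[:, None])
    assert abs(fit.coefficients[0] + 1.0) < 2 * fit.standard_errors[0]
    assert abs(fit.coefficients[1] - 0.8) < 2 * fit.standard_errors[1]


def test_perfect_separation_flagged():
    x = np.concatenate([np.linspace(-2, -0.5, 20), np.linspace(0.5, 2, 20)])
    y = (x > 0).astype(float)
    fit = fit_logistic(y, x[:, None])
    assert fit.separation


def test_rank_deficiency_names_collinear_column(rng):
    x1 = rng.normal(size=100)
    X = pd.DataFrame({"a": x1, "b": 2 * x1})
    y = (rng.random(100) < 0.5).astype(float)
    with pytest.raises(ValueError, match="rank deficient"):
        fit_logistic(y, X)
    with pytest.raises(ValueError, match="constant"):
        fit_logistic(y, pd.DataFrame({"c": np.ones(100)}))


# ----------------------------------------------------------------- stepwise
def _sim_candidates(rng, n=2000, effect=1.0, k_null=5):
    X = pd.DataFrame(rng.normal(size=(n, k_null + 1)),
                     columns=[f"v{i}" for i in range(k_null + 1)])
    eta = -0.3 + effect * X["v0"]
    y = (rng.random(n) < _expit(eta.to_numpy())).astype(float)
    return y, X


def test_stepwise_selects_true_predictor(rng):
    y, X = _sim_candidates(rng)
    model, trace = _stepwise_core(y, X, 0.05, 0.10)
    assert "v0" in model.variables
    assert trace.final_variables() == model.variables


def test_stepwise_empty_candidates_gives_intercept_only(rng):
    df = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(40)],
        "group": [GROUP_CONTROL] * 20 + [GROUP_CASE] * 20})
    model, trace = stepwise_wald(CohortTable(df), "group", [])
    assert model.variables == [] and trace.records == []
    assert model.model_df == 0


def test_stepwise_trace_replay_reproduces_model(rng):
    spec = [VariableSpec("vs", 0.38, 0.04, 0.35, 0.04),
            VariableSpec("noise1", 1.0, 0.5, 1.0, 0.5),
            VariableSpec("noise2", 5.0, 1.0, 5.0, 1.0)]
    tab = simulate_cohort(CohortSimConfig(n_control=66, n_case=66,
                                          variable_specs=spec,
                                          binary_specs=[], seed=8))
    model, trace = stepwise_wald(tab, "group", ["vs", "noise1", "noise2"])
    replayed = replay_trace(tab, "group", ["vs", "noise1", "noise2"], trace)
    assert replayed.variables == model.variables
    np.testing.assert_array_equal(replayed.coefficients, model.coefficients)
    np.testing.assert_array_equal(replayed.standard_errors,
                                  model.standard_errors)


def test_score_test_null_is_uniformish(rng):
    # entry p-values under the null should not be systematically small
    ps = []
    for _ in range(200):
        x = rng.normal(size=300)
        y = (rng.random(300) < 0.4).astype(float)
        p0 = np.full(300, y.mean())
        _, p = _score_test(y, np.empty((300, 0)), p0, x)
        ps.append(p)
    assert 0.02 < np.mean(np.array(ps) < 0.05) < 0.10


# ------------------------------------------------------------- model quality
def test_nagelkerke_worked_example():
    assert nagelkerke_r2(-1.3863, -2.7726, 4) == pytest.approx(2 / 3,
                                                               abs=1e-3)


def test_nagelkerke_null_and_limits(rng):
    assert nagelkerke_r2(-10.0, -10.0, 20) == 0.0
    x = np.concatenate([np.linspace(-3, -1, 30), np.linspace(1, 3, 30)])
    y = (x > 0).astype(float)
    fit = fit_logistic(y, x[:, None])
    assert fit.nagelkerke_r2 > 0.95
    with pytest.raises(ValueError):
        nagelkerke_r2(-5.0, -4.0, 10)


def test_hosmer_lemeshow_needs_enough_groups(rng):
    x = rng.normal(size=100)
    y = (rng.random(100) < _expit(x)).astype(float)
    fit = fit_logistic(y, x[:, None])
    with pytest.raises(ValueError):
        hosmer_lemeshow(fit, g=2)
    res = hosmer_lemeshow(fit, g=10)
    assert res.df == res.n_groups - 2
    assert 0 <= res.p_value <= 1


def test_hosmer_lemeshow_detects_gross_misspecification(rng):
    # strong quadratic truth fitted with a linear logit: HL should reject
    rejections = 0
    for _ in range(40):
        x = rng.normal(size=1500)
        y = (rng.random(1500) < _expit(-2.0 + 2.0 * x * x)).astype(float)
        fit = fit_logistic(y, x[:, None])
        if hosmer_lemeshow(fit).p_value < 0.05:
            rejections += 1
    assert rejections >= 30


# -------------------------------------------------------------------- ROC
def test_roc_worked_example():
    roc = roc_analysis([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0])
    assert roc.auroc == pytest.approx(0.75)


def test_roc_perfect_separation_and_ties():
    assert roc_analysis([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]).auroc == 1.0
    assert roc_analysis([0.5] * 8, [1, 1, 1, 1, 0, 0, 0, 0]).auroc == 0.5


def test_roc_single_class_rejected():
    with pytest.raises(ValueError):
        roc_analysis([0.1, 0.9], [1, 1])


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                min_size=4, max_size=40),
       st.data())
def test_auroc_equals_concordance_probability(scores, data):
    n = len(scores)
    labels = data.draw(st.lists(st.integers(min_value=0, max_value=1),
                                min_size=n, max_size=n))
    if len(set(labels)) < 2:
        return
    scores = np.round(np.asarray(scores), 2)  # force ties regularly
    roc = roc_analysis(scores, labels)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    assert roc.auroc == pytest.approx(wins / (len(pos) * len(neg)),
                                      abs=1e-10)


def test_operating_point_metrics(rng):
    scores = np.array([0.9, 0.8, 0.3, 0.6, 0.2, 0.1])
    labels = np.array([1, 1, 1, 0, 0, 0])
    roc = roc_analysis(scores, labels, classification_cut=0.5)
    op = roc.operating_point
    assert op["sensitivity"] == pytest.approx(2 / 3)
    assert op["specificity"] == pytest.approx(2 / 3)
    assert op["ppv"] == pytest.approx(2 / 3)
    assert op["npv"] == pytest.approx(2 / 3)


# ------------------------------------------------------------------- report
@pytest.fixture(scope="module")
def sim_table():
    return simulate_cohort(CohortSimConfig(seed=17))


def test_report_duplicate_spec_rows_identical(sim_table):
    rep = model_comparison_report(sim_table, [["vs"], ["vs"]])
    assert rep.iloc[0]["auroc"] == rep.iloc[1]["auroc"]
    assert rep.iloc[0]["sensitivity_pct"] == rep.iloc[1]["sensitivity_pct"]


def test_report_superset_improves_on_subset(sim_table):
    # the exact in-sample nesting guarantee is on the likelihood; the
    # concordance (AUROC) can dip by a hair when a weak variable enters
    rep = model_comparison_report(
        sim_table, [["vs"], ["vs", "nt_probnp"],
                    ["vs", "nt_probnp", "adiponectin"]])
    by_vars = {r["variables"]: r["auroc"] for _, r in rep.iterrows()}
    assert by_vars[("vs", "nt_probnp")] >= by_vars[("vs",)] - 0.01
    assert (by_vars[("vs", "nt_probnp", "adiponectin")]
            >= by_vars[("vs", "nt_probnp")] - 0.01)
    y, X = (sim_table.data["group"] == GROUP_CASE).astype(float), \
        sim_table.data
    ll = {}
    for spec in (["vs"], ["vs", "nt_probnp"],
                 ["vs", "nt_probnp", "adiponectin"]):
        ll[tuple(spec)] = fit_logistic(y.to_numpy(),
                                       X[spec]).log_likelihood
    assert ll[("vs", "nt_probnp")] >= ll[("vs",)] - 1e-9
    assert (ll[("vs", "nt_probnp", "adiponectin")]
            >= ll[("vs", "nt_probnp")] - 1e-9)


def test_report_empty_and_unknown_specs(sim_table):
    assert model_comparison_report(sim_table, []).empty
    with pytest.raises(KeyError, match="made_up"):
        model_comparison_report(sim_table, [["made_up"]])
    assert format_report(model_comparison_report(sim_table, [])) == \
        "(no models)"


def test_report_sorted_by_auroc(sim_table):
    rep = model_comparison_report(sim_table, [["age"], ["nt_probnp"], ["vs"]])
    assert list(rep["auroc"]) == sorted(rep["auroc"], reverse=True)


# --------------------------------------------------------------- estimator
def test_screener_sklearn_api(sim_table, rng):
    X = sim_table.data[["vs", "nt_probnp", "adiponectin", "age"]]
    X = X.assign(nt_probnp=np.log10(X["nt_probnp"]),
                 adiponectin=np.log10(X["adiponectin"].clip(lower=0.162)))
    y = (sim_table.data["group"] == GROUP_CASE).astype(int)
    scr = StepwiseLogisticScreener()
    assert clone(scr).get_params()["p_enter"] == 0.05
    scr.fit(X, y)
    assert scr.variables_  # something informative selected
    proba = scr.predict_proba(X)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0)
    pred = scr.predict(X)
    assert set(np.unique(pred)) <= {0, 1}
    assert scr.roc_.auroc > 0.8
    assert 0 <= scr.nagelkerke_r2_ <= 1
    assert scr.score(X, y) > 0.7
    # trace replays to the same variable set
    assert scr.trace_.final_variables() == scr.variables_
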