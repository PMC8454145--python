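"""Diagnostic battery, accuracy metrics, CV, comparison and the ATET grid."""

import numpy as np
import pandas as pd
import pytest

from palcost import causal, diagnostics, schema
from palcost.causal import ATETResult, CostModelFit, fit_cost_glm
from palcost.diagnostics import (
    accuracy_metrics,
    atet_ttest,
    compare_models,
    cross_validate,
    hosmer_lemeshow,
    park_test,
    pearson_test,
    pregibon_link_test,
    sensitivity_grid,
)
from palcost.exceptions import ValidationError


def _gamma_fit(n=2000, seed=0, shape=2.0, predictors=("x",)):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, n)
    mu = np.exp(7.0 + 0.5 * x)
    df = pd.DataFrame({"x": x, "y": rng.gamma(shape, mu / shape)})
    return fit_cost_glm(df, "y", list(predictors)), df


def _manual_fit(mu, y):
    """CostModelFit shell for metric-level tests."""
    mu = pd.Series(np.asarray(mu, dtype=float))
    return CostModelFit(
        coefficients=pd.Series({"const": 0.0}), bse=None, pvalues=None,
        eta=np.log(mu), mu=mu, dispersion=1.0, loglik=0.0, aic=0.0, bic=0.0,
        nobs=len(mu), predictors=[], outcome="y", y=np.asarray(y, dtype=float))


# -- Park test ---------------------------------------------------------------

def test_park_exponent_two_for_gamma_data():
    fit, _ = _gamma_fit(n=6000, seed=1)
    lam, se = park_test(fit)
    assert abs(lam - 2.0) < 2.576 * se


def test_park_all_zero_residuals_rejected():
    fit = _manual_fit([10.0, 20.0], [10.0, 20.0])
    with pytest.raises(ValidationError):
        park_test(fit)


# -- Hosmer-Lemeshow ---------------------------------------------------------

def test_hl_perfect_predictions_zero_statistic():
    fit = _manual_fit([10.0, 20.0, 30.0] * 10, [10.0, 20.0, 30.0] * 10)
    assert hosmer_lemeshow(fit) == (0.0, 1.0)


def test_hl_type_one_error_near_nominal():
    rej = 0
    reps = 30
    for s in range(reps):
        fit, _ = _gamma_fit(n=600, seed=100 + s)
        rej += hosmer_lemeshow(fit)[1] < 0.05
    assert rej / reps <= 0.2  # ~5% nominal, generous binomial allowance


def test_hl_detects_gross_misspecification():
    rng = np.random.default_rng(2)
    n = 2000
    x = rng.normal(0, 1, n)
    mu = np.exp(7 + 0.8 * x - 0.5 * x ** 2)
    df = pd.DataFrame({"x": x, "y": rng.gamma(2.0, mu / 2.0)})
    fit = fit_cost_glm(df, "y", ["x"])      # omits the curvature
    assert hosmer_lemeshow(fit)[1] < 0.05


# -- Pregibon link test ------------------------------------------------------

def test_pregibon_log_link_data_not_flagged():
    fit, _ = _gamma_fit(n=4000, seed=3)
    _, p = pregibon_link_test(fit)
    assert p > 0.01


def test_pregibon_identity_link_data_flagged():
    rng = np.random.default_rng(4)
    n = 3000
    x = rng.normal(0, 1, n)
    mu = 2000 + 3000 * (x - x.min() + 0.1)
    df = pd.DataFrame({"x": x, "y": rng.gamma(2.0, mu / 2.0)})
    fit = fit_cost_glm(df, "y", ["x"])
    _, p = pregibon_link_test(fit)
    assert p < 0.01


def test_pregibon_constant_linear_predictor_degenerate():
    rng = np.random.default_rng(5)
    df = pd.DataFrame({"y": rng.gamma(2.0, 1000, 200)})
    fit = fit_cost_glm(df, "y", [])
    assert pregibon_link_test(fit) == (0.0, 1.0)


# -- Pearson test ------------------------------------------------------------

def test_pearson_residuals_orthogonal_to_predictions():
    rng = np.random.default_rng(6)
    mu = np.exp(rng.normal(7, 0.5, 500))
    resid = rng.normal(0, 100, 500)
    resid -= resid.mean() + (resid @ (mu - mu.mean())) / ((mu - mu.mean()) @ (mu - mu.mean())) * (mu - mu.mean())
    r, _ = pearson_test(_manual_fit(mu, mu + resid))
    assert abs(r) < 1e-10


def test_pearson_underpredicted_upper_tail_positive():
    rng = np.random.default_rng(7)
    mu = np.exp(rng.normal(7, 0.5, 2000))
    y = mu * 1.0
    y[mu > np.quantile(mu, 0.8)] *= 1.5      # systematic underprediction on top
    y += rng.normal(0, 50, 2000)
    r, p = pearson_test(_manual_fit(mu, y))
    assert r > 0 and p < 0.01


# -- accuracy metrics --------------------------------------------------------

def test_accuracy_metrics_hand_example():
    m = accuracy_metrics([110.0, 180.0], [100.0, 200.0])
    assert m.rmse == pytest.approx(np.sqrt(250.0))
    assert m.mape == pytest.approx(10.0)
    assert m.mpe == pytest.approx(0.0, abs=1e-12)


def test_accuracy_metrics_perfect_and_degenerate():
    perfect = accuracy_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert perfect.r2 == pytest.approx(1.0)
    assert (perfect.rmse, perfect.mape, perfect.mpe) == (0.0, 0.0, 0.0)
    constant = accuracy_metrics([5.0, 5.0, 5.0], [4.0, 5.0, 6.0])
    assert constant.r2 == 0.0


def test_accuracy_metrics_rejects_nonpositive_observations():
    with pytest.raises(ValidationError):
        accuracy_metrics([1.0], [0.0])


def test_metrics_match_independent_reference_on_random_vectors():
    rng = np.random.default_rng(8)
    y = rng.gamma(2, 1000, 300)
    mu = y * rng.uniform(0.5, 1.5, 300)
    m = accuracy_metrics(mu, y)
    assert m.rmse == pytest.approx(float(np.sqrt(sum((a - b) ** 2 for a, b in zip(y, mu)) / 300)), rel=1e-10)
    assert m.mape == pytest.approx(float(sum(abs(a - b) / a for a, b in zip(y, mu)) / 3), rel=1e-10)
    assert m.mpe == pytest.approx(float(sum((a - b) / a for a, b in zip(y, mu)) / 3), rel=1e-10)


# -- cross-validation --------------------------------------------------------

def test_leave_one_out_matches_brute_force():
    rng = np.random.default_rng(9)
    n = 12
    x = rng.normal(0, 1, n)
    df = pd.DataFrame({"x": x, "y": rng.gamma(2.0, np.exp(6 + 0.4 * x) / 2.0)})
    cv = cross_validate(df, {"outcome": "y", "predictors": ["x"]}, k=n, seed=0)
    preds = np.empty(n)
    for i in range(n):
        fit = fit_cost_glm(df.drop(index=i), "y", ["x"])
        preds[i] = fit.predict_mu(df.iloc[[i]])[0]
    ref = accuracy_metrics(preds, df["y"].to_numpy())
    assert cv.rmse == pytest.approx(ref.rmse, rel=1e-9)
    assert cv.mape == pytest.approx(ref.mape, rel=1e-9)


def test_cv_same_seed_identical():
    fit_df = _gamma_fit(n=300, seed=10)[1]
    spec = {"outcome": "y", "predictors": ["x"]}
    a = cross_validate(fit_df, spec, k=5, seed=4)
    b = cross_validate(fit_df, spec, k=5, seed=4)
    assert (a.rmse, a.mape, a.mpe) == (b.rmse, b.mape, b.mpe)


def test_out_of_sample_rmse_not_smaller_in_expectation():
    gaps = []
    for s in range(8):
        fit, df = _gamma_fit(n=400, seed=200 + s)
        ins = accuracy_metrics(fit.mu.to_numpy(), fit.y).rmse
        oos = cross_validate(df, {"outcome": "y", "predictors": ["x"]}, k=5, seed=s).rmse
        gaps.append(oos - ins)
    assert np.mean(gaps) > 0


# -- comparison --------------------------------------------------------------

def _report(**over):
    base = dict(park_lambda=2.0, park_se=0.1, hosmer_lemeshow=(1.0, 0.5),
                pregibon=(0.0, 0.9), pearson=(0.0, 0.9), r2=0.2,
                rmse_is=100.0, mape_is=10.0, rmse_os=110.0, mape_os=11.0,
                mpe_os=1.0, aic=500.0, bic=520.0)
    base.update(over)
    return diagnostics.ModelReport(**base)


def _atet(est=-100.0, se=10.0, lo=None, hi=None):
    lo = est - 1.96 * se if lo is None else lo
    hi = est + 1.96 * se if hi is None else hi
    return ATETResult(est, se, lo, hi, 100, 0)


def test_identical_models_all_ties():
    comp = compare_models([_report(), _report()], [_atet(), _atet()], ["a", "b"])
    assert all(w is None for w in comp.winners.values())
    assert comp.tally == {"a": 0, "b": 0}


def test_dominating_model_sweeps_nine_metrics():
    better = _report(r2=0.3, rmse_is=90, mape_is=9, rmse_os=95, mape_os=10,
                     mpe_os=0.5, aic=480, bic=500)
    comp = compare_models([_report(), better], [_atet(se=10), _atet(se=5)], ["a", "b"])
    assert comp.tally == {"a": 0, "b": 9}


def test_random_comparison_matches_brute_force_tally():
    rng = np.random.default_rng(11)
    reports, atets = [], []
    for _ in range(3):
        reports.append(_report(r2=rng.random(), rmse_is=rng.random(), mape_is=rng.random(),
                               rmse_os=rng.random(), mape_os=rng.random(),
                               mpe_os=rng.random() - 0.5, aic=rng.random(), bic=rng.random()))
        atets.append(_atet(se=rng.random() + 0.1))
    comp = compare_models(reports, atets, ["a", "b", "c"])
    assert sum(comp.tally.values()) == sum(w is not None for w in comp.winners.values())
    # brute-force one metric
    rmses = {lab: rep.rmse_is for lab, rep in zip(["a", "b", "c"], reports)}
    assert comp.winners["rmse_is"] == min(rmses, key=rmses.get)


# -- ATET t-test -------------------------------------------------------------

def test_atet_ttest_hand_arithmetic():
    a = _atet(est=-11302.0, se=1524.0)
    b = _atet(est=-9140.0, se=2102.0)
    t, p = atet_ttest(a, b)
    assert t == pytest.approx(-2162.0 / np.sqrt(1524.0 ** 2 + 2102.0 ** 2), rel=1e-12)
    assert t == pytest.approx(-0.8327, abs=5e-4)
    assert p > 0.05


def test_atet_ttest_identical_estimates():
    a = _atet()
    assert atet_ttest(a, a) == (0.0, 1.0)


def test_paired_se_smaller_under_positive_correlation():
    rng = np.random.default_rng(12)
    ra = rng.normal(0, 1, 500)
    rb = ra + rng.normal(0, 0.3, 500)      # strongly correlated replicates
    a = _atet(est=0.0, se=float(np.std(ra, ddof=1)))
    b = _atet(est=0.5, se=float(np.std(rb, ddof=1)))
    t_pair, _ = atet_ttest(a, b, paired_replicates=(ra, rb))
    t_indep, _ = atet_ttest(a, b)
    assert abs(t_pair) > abs(t_indep)      # smaller SE -> larger |t|


# -- sensitivity grid --------------------------------------------------------

def test_grid_single_cell_matches_plain_pipeline(model_frame_2000):
    mf, _ = model_frame_2000
    tert = pd.Series("all", index=mf.index)
    grid = sensitivity_grid(mf, [3], tert, schema.BASE_COVARIATES)
    direct = causal._atet_chain(
        mf["direct_cost"].to_numpy(), mf["t1"].to_numpy(),
        mf[schema.BASE_COVARIATES].to_numpy(float),
        mf[schema.BASE_COVARIATES].to_numpy(float))
    assert grid["atet"].iloc[0] == pytest.approx(direct, rel=1e-9)


def test_grid_empty_cell_flagged_missing(model_frame_2000):
    mf, _ = model_frame_2000
    sub = mf.copy()
    sub["pc_day"] = pd.NA                     # nobody treated at any d
    sub["pc_day"] = sub["pc_day"].astype("Int64")
    tert = pd.Series("all", index=sub.index)
    grid = sensitivity_grid(sub, [3], tert, schema.BASE_COVARIATES)
    assert np.isnan(grid["atet"].iloc[0])
    assert grid["n_treated"].iloc[0] == 0
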