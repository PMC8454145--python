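"""Propensity/IPTW, gamma GLM, ATET and bootstrap contracts."""

import warnings

import numpy as np
import pandas as pd
import pytest

import palcost
from palcost import causal, schema, treat
from palcost.causal import (
    atet_weights,
    bootstrap_atet,
    estimate_atet,
    fit_cost_glm,
    fit_propensity,
    select_covariates,
    standardized_difference,
)
from palcost.exceptions import SeparationError, ValidationError


# -- propensity --------------------------------------------------------------

def test_null_propensity_scores_near_marginal_rate():
    rng = np.random.default_rng(0)
    n = 4000
    df = pd.DataFrame({"x": rng.normal(0, 1, n), "t": rng.random(n) < 0.3})
    df["t"] = df["t"].astype(int)
    fit = fit_propensity(df, "t", ["x"])
    assert fit.score.mean() == pytest.approx(0.3, abs=0.03)
    assert fit.score.std() < 0.05


def test_atet_weight_closed_forms():
    p = np.array([0.5, 0.8, 0.2])
    t = np.array([0, 0, 1])
    np.testing.assert_allclose(atet_weights(p, t), [1.0, 4.0, 1.0])


def test_treated_weights_exactly_one(model_frame_2000):
    mf, _ = model_frame_2000
    fit = fit_propensity(mf, "t1", schema.BASE_COVARIATES)
    treated = mf["t1"] == 1
    assert (fit.weights[treated] == 1.0).all()
    assert ((fit.score > 0) & (fit.score < 1)).all()


def test_single_class_treatment_rejected():
    df = pd.DataFrame({"x": [1.0, 2.0], "t": [1, 1]})
    with pytest.raises(ValidationError):
        fit_propensity(df, "t", ["x"])


def test_perfect_separation_detected():
    rng = np.random.default_rng(1)
    n = 200
    t = np.repeat([0, 1], n // 2)
    df = pd.DataFrame({"x": t + 0.01 * rng.normal(size=n), "t": t})
    with pytest.raises(SeparationError):
        fit_propensity(df, "t", ["x"])


# -- standardized differences ------------------------------------------------

def test_standardized_difference_identical_groups_zero():
    x = np.array([1, 0, 1, 0], dtype=float)
    t = np.array([1, 1, 0, 0])         # both groups 50% prevalent
    assert standardized_difference(x, t) == pytest.approx(0.0, abs=1e-12)


def _binary_groups(p1, n1, p2, n2):
    x = np.concatenate([np.repeat([1.0, 0.0], [round(p1 * n1), n1 - round(p1 * n1)]),
                        np.repeat([1.0, 0.0], [round(p2 * n2), n2 - round(p2 * n2)])])
    t = np.repeat([1, 0], [n1, n2])
    return x, t


def test_binary_standardized_difference_formula():
    x, t = _binary_groups(0.47, 100, 0.20, 100)
    d = standardized_difference(x, t)
    expected = abs(0.47 - 0.20) / np.sqrt((0.47 * 0.53 + 0.20 * 0.80) / 2) * 100
    assert d == pytest.approx(expected, abs=1e-9)


def test_continuous_standardized_difference_formula():
    rng = np.random.default_rng(2)
    a, b = rng.normal(5, 2, 300), rng.normal(4, 1, 300)
    x = np.concatenate([a, b])
    t = np.repeat([1, 0], 300)
    expected = abs(a.mean() - b.mean()) / np.sqrt((a.var() + b.var()) / 2) * 100
    assert standardized_difference(x, t) == pytest.approx(expected, rel=1e-9)


def test_unit_weights_match_unweighted(model_frame_2000):
    mf, _ = model_frame_2000
    x = mf["charlson_score"].to_numpy(dtype=float)
    t = mf["t1"].to_numpy()
    w = np.ones(len(mf))
    assert standardized_difference(x, t) == pytest.approx(standardized_difference(x, t, w))


def test_empty_group_rejected():
    with pytest.raises(ValidationError):
        standardized_difference([1.0, 2.0], [1, 1])


# -- gamma GLM ---------------------------------------------------------------

def test_intercept_only_constant_outcome():
    df = pd.DataFrame({"y": np.full(50, 1234.5)})
    fit = fit_cost_glm(df, "y", [])
    assert fit.coefficients["const"] == pytest.approx(np.log(1234.5), rel=1e-8)
    np.testing.assert_allclose(fit.mu, 1234.5, rtol=1e-8)


def test_binary_predictor_coefficient_is_log_mean_ratio():
    rng = np.random.default_rng(3)
    t = np.repeat([0, 1], 400)
    y = rng.gamma(2.0, np.where(t == 1, 3000, 5000) / 2.0)
    df = pd.DataFrame({"t": t, "y": y})
    fit = fit_cost_glm(df, "y", ["t"])
    m1, m0 = y[t == 1].mean(), y[t == 0].mean()
    assert fit.coefficients["t"] == pytest.approx(np.log(m1 / m0), rel=1e-6)


def test_simulated_gamma_coefficients_recovered():
    rng = np.random.default_rng(4)
    n = 5000
    x = rng.normal(0, 1, n)
    t = (rng.random(n) < 0.4).astype(int)
    mu = np.exp(7.0 + 0.5 * x - 0.3 * t)
    df = pd.DataFrame({"x": x, "t": t, "y": rng.gamma(2.0, mu / 2.0)})
    fit = fit_cost_glm(df, "y", ["x", "t"])
    for name, true in [("x", 0.5), ("t", -0.3)]:
        assert abs(fit.coefficients[name] - true) < 3 * fit.bse[name]


def test_nonpositive_outcome_rejected():
    df = pd.DataFrame({"y": [10.0, -1.0], "x": [0.0, 1.0]})
    with pytest.raises(ValidationError):
        fit_cost_glm(df, "y", ["x"])


def test_collinearity_warned():
    rng = np.random.default_rng(5)
    x = rng.normal(0, 1, 200)
    df = pd.DataFrame({"x": x, "x2": 2 * x + 1e-4 * rng.normal(size=200),
                       "y": np.exp(7 + 0.1 * x) * rng.gamma(2, 0.5, 200)})
    with pytest.warns(UserWarning, match="condition number"):
        fit_cost_glm(df, "y", ["x", "x2"])


# -- ATET --------------------------------------------------------------------

def test_atet_closed_form_treatment_only_model():
    rng = np.random.default_rng(6)
    t = np.repeat([0, 1], 300)
    y = rng.gamma(2.0, np.where(t == 1, 8000, 11000) / 2.0)
    df = pd.DataFrame({"t": t, "y": y})
    fit = fit_cost_glm(df, "y", ["t"])
    a, b = fit.coefficients["const"], fit.coefficients["t"]
    atet = estimate_atet(fit, df, "t")
    assert atet == pytest.approx(np.exp(a + b) - np.exp(a), rel=1e-9)
    # unweighted two-group gamma GLM ATET equals the difference of group means
    assert atet == pytest.approx(y[t == 1].mean() - y[t == 0].mean(), rel=1e-6)


def test_zero_treatment_coefficient_gives_zero_atet():
    df = pd.DataFrame({"t": [0, 1] * 100, "y": np.full(200, 5000.0)})
    fit = fit_cost_glm(df, "y", ["t"])
    assert estimate_atet(fit, df, "t") == pytest.approx(0.0, abs=1e-6)


def test_atet_requires_treatment_in_predictors(model_frame_2000):
    mf, _ = model_frame_2000
    fit = fit_cost_glm(mf, "direct_cost", schema.BASE_COVARIATES)
    with pytest.raises(ValidationError):
        estimate_atet(fit, mf, "t1")


# -- bootstrap ---------------------------------------------------------------

def _small_frame(n=400, seed=8):
    df, _ = palcost.generate_cohort(
        palcost.GeneratorParams(n_subjects=n, seed=seed, repeat_admission_rate=0.0))
    mf = schema.prepare_model_frame(df)
    mf["t1"] = treat.assign_t1_cohort(mf).assignment
    return mf


def test_bootstrap_same_seed_reproducible():
    mf = _small_frame()
    kwargs = dict(propensity_covariates=schema.BASE_COVARIATES, n_reps=25, seed=99)
    a = bootstrap_atet(mf, "t1", ["t1"] + schema.BASE_COVARIATES, **kwargs)
    b = bootstrap_atet(mf, "t1", ["t1"] + schema.BASE_COVARIATES, **kwargs)
    assert a.estimate == b.estimate
    assert a.bootstrap_se == b.bootstrap_se
    assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)


def test_bootstrap_degenerate_zero_variance_outcome():
    rng = np.random.default_rng(10)
    df = pd.DataFrame({"t1": rng.integers(0, 2, 120), "direct_cost": 5000.0})
    res = bootstrap_atet(df, "t1", ["t1"], propensity_covariates=[], n_reps=20, seed=1)
    assert res.bootstrap_se == pytest.approx(0.0, abs=1e-8)
    assert res.ci_width == pytest.approx(0.0, abs=1e-6)


def test_bootstrap_se_stable_in_replication_count():
    mf = _small_frame()
    preds = ["t1"] + schema.BASE_COVARIATES
    a = bootstrap_atet(mf, "t1", preds, propensity_covariates=schema.BASE_COVARIATES,
                       n_reps=100, seed=7)
    b = bootstrap_atet(mf, "t1", preds, propensity_covariates=schema.BASE_COVARIATES,
                       n_reps=300, seed=8)
    assert a.bootstrap_se == pytest.approx(b.bootstrap_se, rel=0.4)


def test_bootstrap_ci_brackets_estimate():
    mf = _small_frame(seed=9)
    res = bootstrap_atet(mf, "t1", ["t1"] + schema.BASE_COVARIATES,
                         propensity_covariates=schema.BASE_COVARIATES, n_reps=30, seed=2)
    assert res.ci_low <= res.estimate <= res.ci_high
    assert res.ci_width == pytest.approx(res.ci_high - res.ci_low)


# -- covariate selection -----------------------------------------------------

def test_selection_keeps_signal_drops_noise():
    rng = np.random.default_rng(11)
    n = 3000
    x = rng.normal(0, 1, n)
    z = rng.normal(0, 1, n)
    y = rng.gamma(2.0, np.exp(7 + 0.6 * x) / 2.0)
    df = pd.DataFrame({"x": x, "z": z, "y": y})
    res = select_covariates(df, ["x", "z"], outcome="y")
    assert any(name.startswith("x") for name in res.retained)
    assert not any(name.startswith("z") for name in res.retained)


def test_binarisation_rejected_when_it_loses_signal():
    rng = np.random.default_rng(12)
    n = 4000
    x = rng.normal(0, 1, n)
    y = rng.gamma(4.0, np.exp(7 + 0.8 * x) / 4.0)
    res = select_covariates(pd.DataFrame({"x": x, "y": y}), ["x"], outcome="y")
    assert res.retained == ["x"]
    assert res.binarised == {}


def test_binarisation_kept_for_threshold_effect():
    rng = np.random.default_rng(13)
    n = 4000
    x = rng.uniform(0, 1, n)
    g = (x > np.median(x)).astype(int)     # the true effect is a threshold
    y = rng.gamma(4.0, np.exp(7 + 0.5 * g) / 4.0)
    res = select_covariates(pd.DataFrame({"x": x, "y": y}), ["x"], outcome="y")
    assert list(res.binarised) == ["x"]
    assert res.retained == [res.binarised["x"]]


def test_empty_effect_world_warns_intercept_only():
    rng = np.random.default_rng(1)
    df = pd.DataFrame({"z": rng.normal(0, 1, 500),
                       "y": rng.gamma(2.0, 1000.0, 500)})
    with pytest.warns(UserWarning, match="intercept-only"):
        res = select_covariates(df, ["z"], outcome="y")
    assert res.retained == []
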