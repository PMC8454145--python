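"""Model diagnostics, accuracy metrics, comparison harness and sensitivity grid.

The diagnostic battery follows the health-econometrics toolkit for choosing
and checking a cost-regression family and link:

* modified Park test — regress the log squared raw residual on the log
  prediction; the slope identifies the variance-to-mean power (0 constant,
  1 Poisson-like, 2 gamma, 3 inverse-Gaussian);
* Hosmer–Lemeshow-style grouped calibration — group subjects by prediction
  deciles and jointly test whether group mean residuals are zero (F test);
* Pregibon link test — refit on the linear predictor and its square; a
  significant squared term flags a mis-specified link;
* Pearson correlation test between raw residuals and predictions.

Model accuracy is summarised by R² (squared Pearson correlation of observed
and predicted costs on the raw scale), RMSE, MAPE and MPE, in sample and via
seed-controlled k-fold cross-validation out of sample. The comparison
harness tallies per-metric winners over the nine evaluative metrics, and the
sensitivity grid re-estimates the ATET across fixed-day thresholds within
predicted-LOS tertiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import causal, treat
from .causal import ATETResult, CostModelFit
from .exceptions import ValidationError


# ---------------------------------------------------------------------------
# family / link battery
# ---------------------------------------------------------------------------

def park_test(fit: CostModelFit) -> tuple[float, float]:
    """Modified Park test: slope of ln(residual²) on ln(μ̂) and its SE."""
    resid = fit.residuals
    mu = fit.mu.to_numpy()
    keep = resid ** 2 > 0
    if not keep.any():
        raise ValidationError("all residuals are zero; Park test undefined")
    if keep.sum() < len(resid):
        warnings.warn(f"dropping {len(resid) - keep.sum()} zero residuals in Park test")
    res = sm.OLS(np.log(resid[keep] ** 2), sm.add_constant(np.log(mu[keep]))).fit()
    return float(res.params[1]), float(res.bse[1])


def hosmer_lemeshow(fit: CostModelFit, n_groups: int = 10) -> tuple[float, float]:
    """Grouped calibration test over prediction deciles.

    Subjects are grouped by deciles of the prediction; within each group the
    mean raw residual is standardised by its own estimated standard error
    (per-group variances, since cost residual variance grows with the mean),
    and the squared standardised discrepancies are summed. Under a correctly
    specified mean model the statistic is approximately chi-square with one
    degree of freedom per group. Groups thinner than 2 subjects trigger a
    reduction with a warning; perfect predictions give (0, 1).
    """
    if n_groups < 2:
        raise ValidationError("n_groups must be >= 2")
    resid = fit.residuals
    mu = fit.mu.to_numpy()
    if np.allclose(resid, 0):
        return 0.0, 1.0
    if np.ptp(mu) < 1e-12:  # constant predictions: single overall-bias group
        groups = np.zeros(len(mu), dtype=int)
    else:
        groups = pd.qcut(mu, q=n_groups, labels=False, duplicates="drop")
    g = int(groups.max()) + 1
    sizes = np.bincount(groups, minlength=g)
    while g > 2 and sizes.min() < 2:
        g -= 1
        warnings.warn(f"reducing Hosmer–Lemeshow groups to {g} (thin group)")
        groups = pd.qcut(mu, q=g, labels=False, duplicates="drop")
        g = int(groups.max()) + 1
        sizes = np.bincount(groups, minlength=g)
    stat = 0.0
    for k in range(g):
        rk = resid[groups == k]
        vk = rk.var(ddof=1)
        if vk == 0:
            if abs(rk.mean()) > 0:
                return float("inf"), 0.0
            continue
        stat += rk.mean() ** 2 / (vk / len(rk))
    p = float(stats.chi2.sf(stat, g))
    return float(stat), p


def pregibon_link_test(fit: CostModelFit) -> tuple[float, float]:
    """Pregibon link test: refit on η̂ and η̂²; returns (coef on η̂², p).

    A coefficient near zero indicates the log link is adequate. Degenerate
    fits with a constant linear predictor return (0, 1).
    """
    eta = fit.eta.to_numpy()
    if np.ptp(eta) < 1e-12:
        return 0.0, 1.0
    X = sm.add_constant(np.column_stack([eta, eta ** 2]))
    res = causal._fit_gamma_glm(fit.y, X, fit.weights)
    return float(res.params[2]), float(res.pvalues[2])


def pearson_test(fit: CostModelFit) -> tuple[float, float]:
    """Correlation between raw residuals and predictions, with its p-value."""
    r, p = stats.pearsonr(fit.residuals, fit.mu.to_numpy())
    return float(r), float(p)


# ---------------------------------------------------------------------------
# accuracy metrics
# ---------------------------------------------------------------------------

@dataclass
class AccuracyMetrics:
    r2: float
    rmse: float
    mape: float
    mpe: float


def accuracy_metrics(predictions, observations) -> AccuracyMetrics:
    """R², RMSE, MAPE and MPE of predictions against positive observations.

    ``mape = mean |y-μ̂|/y × 100``; ``mpe = mean (y-μ̂)/y × 100``. R² is the
    squared Pearson correlation of observed and predicted values (0 when the
    predictions are constant).
    """
    mu = np.asarray(predictions, dtype=float)
    y = np.asarray(observations, dtype=float)
    if mu.shape != y.shape:
        raise ValidationError("predictions and observations must have equal length")
    if (y <= 0).any():
        raise ValidationError("observations must be strictly positive for MAPE/MPE")
    rmse = float(np.sqrt(np.mean((y - mu) ** 2)))
    mape = float(np.mean(np.abs(y - mu) / y) * 100.0)
    mpe = float(np.mean((y - mu) / y) * 100.0)
    if np.ptp(mu) < 1e-300 or np.ptp(y) < 1e-300:
        r2 = 0.0 if rmse > 0 else 1.0
    else:
        r2 = float(stats.pearsonr(y, mu)[0] ** 2)
    return AccuracyMetrics(r2, rmse, mape, mpe)


def cross_validate(records: pd.DataFrame, model_spec: Mapping, k: int = 10,
                   seed: int = 0) -> AccuracyMetrics:
    """Seed-reproducible k-fold cross-validation of a cost model.

    ``model_spec`` carries ``outcome``, ``predictors`` and optionally
    ``treatment`` + ``propensity_covariates`` (in which case IPTW weights are
    re-estimated inside each training fold). Held-out predictions are pooled
    before computing the metrics.
    """
    n = len(records)
    if not 2 <= k <= n:
        raise ValidationError("k must be between 2 and n")
    outcome = model_spec.get("outcome", "direct_cost")
    predictors = list(model_spec["predictors"])
    treatment = model_spec.get("treatment")
    prop_covs = model_spec.get("propensity_covariates")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    preds = np.empty(n)
    for fold in folds:
        test_mask = np.zeros(n, dtype=bool)
        test_mask[fold] = True
        train = records.iloc[~test_mask]
        test = records.iloc[test_mask]
        w = None
        if treatment is not None and prop_covs is not None:
            w = causal.fit_propensity(train, treatment, prop_covs).weights
        fit = causal.fit_cost_glm(train, outcome, predictors, weights=w)
        preds[test_mask] = fit.predict_mu(test)
    return accuracy_metrics(preds, records[outcome].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# model reports and comparison
# ---------------------------------------------------------------------------

@dataclass
class ModelReport:
    """Diagnostic battery plus in/out-of-sample accuracy for one model."""

    park_lambda: float
    park_se: float
    hosmer_lemeshow: tuple[float, float]
    pregibon: tuple[float, float]
    pearson: tuple[float, float]
    r2: float
    rmse_is: float
    mape_is: float
    rmse_os: float
    mape_os: float
    mpe_os: float
    aic: float
    bic: float

    def to_dict(self) -> dict:
        return asdict(self)


def model_report(fit: CostModelFit, records: pd.DataFrame,
                 model_spec: Mapping | None = None, k: int = 10,
                 seed: int = 0) -> ModelReport:
    """Assemble the full diagnostic battery and accuracy metrics for a fit."""
    in_sample = accuracy_metrics(fit.mu.to_numpy(), fit.y)
    spec = dict(model_spec or {})
    spec.setdefault("outcome", fit.outcome)
    spec.setdefault("predictors", fit.predictors)
    oos = cross_validate(records, spec, k=k, seed=seed)
    return ModelReport(
        park_lambda=park_test(fit)[0],
        park_se=park_test(fit)[1],
        hosmer_lemeshow=hosmer_lemeshow(fit),
        pregibon=pregibon_link_test(fit),
        pearson=pearson_test(fit),
        r2=in_sample.r2,
        rmse_is=in_sample.rmse,
        mape_is=in_sample.mape,
        rmse_os=oos.rmse,
        mape_os=oos.mape,
        mpe_os=oos.mpe,
        aic=fit.aic,
        bic=fit.bic,
    )


#: The nine evaluative metrics and their winning direction.
COMPARISON_METRICS = {
    "r2": "higher",
    "rmse_is": "lower",
    "mape_is": "lower",
    "rmse_os": "lower",
    "mape_os": "lower",
    "abs_mpe_os": "lower",
    "aic": "lower",
    "bic": "lower",
    "ci_width": "lower",
}


@dataclass
class ComparisonResult:
    table: pd.DataFrame
    winners: dict[str, str | None]   # metric -> winning model label (None = tie)
    tally: dict[str, int]            # model label -> number of metrics won


def compare_models(reports: Sequence[ModelReport], atets: Sequence[ATETResult],
                   labels: Sequence[str] | None = None) -> ComparisonResult:
    """Tally per-metric winners over the nine evaluative metrics."""
    if len(reports) != len(atets):
        raise ValidationError("reports and atets must align")
    labels = list(labels) if labels else [f"model_{i}" for i in range(len(reports))]
    rows = {}
    for lab, rep, at in zip(labels, reports, atets):
        rows[lab] = {
            "r2": rep.r2, "rmse_is": rep.rmse_is, "mape_is": rep.mape_is,
            "rmse_os": rep.rmse_os, "mape_os": rep.mape_os,
            "abs_mpe_os": abs(rep.mpe_os), "aic": rep.aic, "bic": rep.bic,
            "ci_width": at.ci_width,
            "atet": at.estimate, "ci_low": at.ci_low, "ci_high": at.ci_high,
        }
    table = pd.DataFrame(rows).T
    winners: dict[str, str | None] = {}
    tally = {lab: 0 for lab in labels}
    for metric, direction in COMPARISON_METRICS.items():
        col = table[metric]
        best = col.min() if direction == "lower" else col.max()
        best_labels = [lab for lab in labels if col[lab] == best]
        if len(best_labels) == 1:
            winners[metric] = best_labels[0]
            tally[best_labels[0]] += 1
        else:
            winners[metric] = None
    return ComparisonResult(table, winners, tally)


def atet_ttest(a: ATETResult, b: ATETResult,
               paired_replicates: tuple[np.ndarray, np.ndarray] | None = None
               ) -> tuple[float, float]:
    """Two-sided test of equal ATETs from two models.

    With paired bootstrap replicates the SE of the difference is the standard
    deviation of per-replicate differences; otherwise the independent-SE
    formula ``sqrt(SE_a² + SE_b²)``. The p-value uses the normal reference
    distribution (bootstrap-based SEs).
    """
    if paired_replicates is not None:
        ra, rb = paired_replicates
        if len(ra) != len(rb):
            raise ValidationError("paired replicate vectors must align")
        se = float(np.std(np.asarray(ra) - np.asarray(rb), ddof=1))
    else:
        se = float(np.sqrt(a.bootstrap_se ** 2 + b.bootstrap_se ** 2))
    if se == 0:
        return (0.0, 1.0) if a.estimate == b.estimate else (float("inf"), 0.0)
    t = (a.estimate - b.estimate) / se
    return float(t), float(2 * stats.norm.sf(abs(t)))


# ---------------------------------------------------------------------------
# sensitivity grid
# ---------------------------------------------------------------------------

def sensitivity_grid(records: pd.DataFrame, d_values: Sequence[int],
                     tertiles: pd.Series, predictors: list[str],
                     propensity_covariates: list[str] | None = None,
                     outcome: str = "direct_cost",
                     treatment_col: str = "_t_grid",
                     min_treated: int = 10) -> pd.DataFrame:
    """ATET across fixed-day thresholds within predicted-LOS tertiles.

    For each (d, tertile) cell the sample is restricted to the tertile, the
    fixed-day rule with threshold ``d`` defines treatment, and the IPTW +
    gamma-GLM point ATET is estimated. Cells with fewer than ``min_treated``
    treated subjects (or no controls) are flagged missing (NaN), never zero.
    Returns a long-format DataFrame (d, tertile, atet, n, n_treated).
    """
    if not records.index.equals(tertiles.index):
        raise ValidationError("tertile labels must be indexed like records")
    prop = propensity_covariates or predictors
    rows = []
    for tert in pd.unique(tertiles):
        sub = records[tertiles == tert]
        for d in d_values:
            assign = treat.assign_t1_cohort(sub, d=d).assignment
            n_treated = int(assign.sum())
            cell = {"d": d, "tertile": tert, "n": len(sub), "n_treated": n_treated}
            if n_treated < min_treated or n_treated == len(sub):
                cell["atet"] = float("nan")
            else:
                y = sub[outcome].to_numpy(dtype=float)
                t = assign.to_numpy()
                Xg = sub[[c for c in predictors if c != treatment_col]].to_numpy(dtype=float)
                Xp = sub[prop].to_numpy(dtype=float)
                try:
                    cell["atet"] = causal._atet_chain(y, t, Xg, Xp)
                except Exception:
                    cell["atet"] = float("nan")
            rows.append(cell)
    return pd.DataFrame(rows)


def plot_sensitivity_grid(grid: pd.DataFrame, ax=None):
    """Line plot of ATET against d, one line per predicted-LOS tertile."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for tert, sub in grid.groupby("tertile"):
        ax.plot(sub["d"], sub["atet"], marker="o", label=str(tert))
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("treatment threshold d (days)")
    ax.set_ylabel("ATET (US$)")
    ax.legend(title="predicted-LOS tertile")
    return ax
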