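"""Propensity scores, IPTW, gamma/log-link cost models and ATET estimation.

The estimation chain mirrors standard practice in observational hospital-cost
studies: a logistic propensity model for treatment given baseline covariates;
inverse-probability-of-treatment weights targeting the average treatment
effect on the treated (ATET weighting: treated weight 1, control weight
p/(1-p)); a generalized linear model for cost with a gamma distribution and
log link, fit with those weights; and the ATET computed by recycled
predictions — each treated subject is predicted under both treatment states
from the one fitted model and the differences averaged. Uncertainty comes
from a subject-level bootstrap that refits the whole chain (propensity model
included) in every replicate, so weight-estimation uncertainty propagates
into the standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .exceptions import ConvergenceError, SeparationError, ValidationError

_COND_WARN = 1e4  # condition-number threshold for a collinearity warning


# ---------------------------------------------------------------------------
# propensity
# ---------------------------------------------------------------------------

@dataclass
class PropensityFit:
    """Logistic propensity fit with ATET weights.

    Treated subjects carry weight exactly 1; controls carry p/(1-p), which
    reweights the comparison group to the treated population.
    """

    coefficients: pd.Series
    score: pd.Series    # P(T=1 | X), strictly inside (0, 1)
    weights: pd.Series


_RIDGE = 1e-6  # tiny L2 stabiliser; matches the MLE to ~1e-6 on regular data


def _fit_logit(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Logistic fit by penalized IRLS with step halving.

    A tiny ridge penalty keeps the Hessian invertible when a rare covariate
    level is pure in one class (directional quasi-separation, common in
    bootstrap resamples); on regular data the result coincides with the MLE
    to numerical precision. Raises ConvergenceError if IRLS stalls.
    """
    n, k = X.shape
    beta = np.zeros(k)

    def pen_llf(b):
        eta = np.clip(X @ b, -500, 500)
        return float(y @ eta - np.logaddexp(0.0, eta).sum() - 0.5 * _RIDGE * (b @ b))

    llf = pen_llf(beta)
    for _ in range(200):
        p = expit(X @ beta)
        w = p * (1.0 - p) + 1e-12
        grad = X.T @ (y - p) - _RIDGE * beta
        hess = (X * w[:, None]).T @ X + _RIDGE * np.eye(k)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise ConvergenceError(f"propensity fit failed: {exc}") from exc
        new = beta + step
        new_llf = pen_llf(new)
        halvings = 0
        while new_llf < llf - 1e-12 and halvings < 30:
            step /= 2.0
            new = beta + step
            new_llf = pen_llf(new)
            halvings += 1
        beta, llf = new, new_llf
        if np.max(np.abs(step)) < 1e-9:
            return beta
    raise ConvergenceError("propensity IRLS did not converge")


def _propensity_probs(t: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fitted propensities with separation diagnostics.

    Controls predicted with probability ~1 make ATET weights unbounded, and a
    model that classifies the two groups perfectly carries no overlap; both
    raise SeparationError. Controls at probability ~0 are benign (their ATET
    weight vanishes).
    """
    params = _fit_logit(t, X)
    p = np.clip(expit(X @ params), 1e-12, 1.0 - 1e-12)
    controls = t == 0
    if p[controls].max() > 1.0 - 1e-8:
        raise SeparationError("control subject with fitted propensity ~1; ATET weights unbounded")
    if p[~controls].min() > 0.99 and p[controls].max() < 0.01:
        raise SeparationError("perfect separation: propensity model classifies groups exactly")
    return params, p


def atet_weights(score: np.ndarray, treated: np.ndarray) -> np.ndarray:
    """ATET weighting: treated weight 1, control weight p/(1-p)."""
    score = np.asarray(score, dtype=float)
    treated = np.asarray(treated).astype(bool)
    w = np.where(treated, 1.0, score / (1.0 - score))
    return w


def fit_propensity(records: pd.DataFrame, treatment, covariates: list[str]) -> PropensityFit:
    """Fit a logistic propensity model and ATET weights.

    ``treatment`` is a column name or a 0/1 array aligned to ``records``.
    """
    t = records[treatment].to_numpy() if isinstance(treatment, str) else np.asarray(treatment)
    t = t.astype(int)
    if len(np.unique(t)) < 2:
        raise ValidationError("both treatment classes must be present")
    X = sm.add_constant(records[covariates].to_numpy(dtype=float), has_constant="add")
    params, p = _propensity_probs(t, X)
    score = pd.Series(p, index=records.index)
    weights = pd.Series(atet_weights(p, t), index=records.index)
    coef = pd.Series(params, index=["const"] + list(covariates))
    return PropensityFit(coef, score, weights)


# ---------------------------------------------------------------------------
# balance
# ---------------------------------------------------------------------------

def _wmean_var(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    m = np.average(x, weights=w)
    v = np.average((x - m) ** 2, weights=w)
    return float(m), float(v)


def standardized_difference(values, treatment, weights=None) -> float:
    """Absolute standardized difference between groups, in percent.

    Binary covariates compare prevalences with the pooled-proportion
    denominator ``sqrt((p1(1-p1) + p2(1-p2))/2)``; continuous covariates
    compare means with ``sqrt((s1^2 + s2^2)/2)``. Weighted versions use
    weighted moments. Sample size does not enter.
    """
    x = np.asarray(values, dtype=float)
    t = np.asarray(treatment).astype(bool)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if t.sum() == 0 or (~t).sum() == 0:
        raise ValidationError("both groups must be non-empty")
    binary = set(np.unique(x)) <= {0.0, 1.0}
    m1, v1 = _wmean_var(x[t], w[t])
    m0, v0 = _wmean_var(x[~t], w[~t])
    if binary:
        v1, v0 = m1 * (1 - m1), m0 * (1 - m0)
    denom = np.sqrt((v1 + v0) / 2.0)
    if denom == 0:
        return 0.0 if m1 == m0 else float("inf")
    return float(abs(m1 - m0) / denom * 100.0)


def balance_table(records: pd.DataFrame, treatment, covariates: list[str],
                  weights: pd.Series | None = None) -> pd.DataFrame:
    """Unweighted and weighted standardized differences per covariate."""
    t = records[treatment].to_numpy() if isinstance(treatment, str) else np.asarray(treatment)
    rows = []
    for c in covariates:
        x = records[c].to_numpy(dtype=float)
        row = {"covariate": c,
               "unweighted_pct": standardized_difference(x, t)}
        if weights is not None:
            row["weighted_pct"] = standardized_difference(x, t, weights.to_numpy())
        rows.append(row)
    return pd.DataFrame(rows).set_index("covariate")


# ---------------------------------------------------------------------------
# gamma GLM cost model
# ---------------------------------------------------------------------------

@dataclass
class CostModelFit:
    """Converged gamma/log-link GLM for total direct cost."""

    coefficients: pd.Series          # intercept under "const"
    bse: pd.Series
    pvalues: pd.Series
    eta: pd.Series                   # linear predictor per subject
    mu: pd.Series                    # exp(eta)
    dispersion: float                # Pearson-based scale estimate
    loglik: float
    aic: float
    bic: float
    nobs: int
    predictors: list[str]
    outcome: str
    y: np.ndarray = field(repr=False, default=None)
    weights: np.ndarray = field(repr=False, default=None)
    results: object = field(repr=False, default=None)

    def predict_mu(self, records: pd.DataFrame) -> np.ndarray:
        X = records[self.predictors].to_numpy(dtype=float)
        eta = self.coefficients["const"] + X @ self.coefficients[self.predictors].to_numpy()
        return np.exp(eta)

    @property
    def residuals(self) -> np.ndarray:
        return self.y - self.mu.to_numpy()


def _fit_gamma_glm(y: np.ndarray, X: np.ndarray, w: np.ndarray | None):
    model = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log()),
                   var_weights=w)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels domain warnings on tiny weights
        res = model.fit(maxiter=200, tol=1e-10)
    if not res.converged:
        raise ConvergenceError("gamma GLM did not converge (IRLS iteration limit)")
    return res


def fit_cost_glm(records: pd.DataFrame, outcome: str = "direct_cost",
                 predictors: list[str] | None = None,
                 weights: pd.Series | None = None) -> CostModelFit:
    """Fit a gamma GLM with log link for a positive cost outcome.

    AIC and BIC are computed from the attained log-likelihood
    (``-2 llf + 2k`` and ``-2 llf + k ln n``). A design condition number
    above 1e8 triggers a collinearity warning.
    """
    if predictors is None:
        raise ValidationError("predictors must be given explicitly")
    y = records[outcome].to_numpy(dtype=float)
    if (y <= 0).any():
        raise ValidationError("cost outcome must be strictly positive for a gamma GLM")
    X = sm.add_constant(records[predictors].to_numpy(dtype=float), has_constant="add")
    sd = X.std(axis=0)
    scaled = X / np.where(sd > 0, sd, 1.0)
    cond = np.linalg.cond(scaled)
    if cond > _COND_WARN:
        warnings.warn(f"design condition number {cond:.3g} exceeds {_COND_WARN:.0e}; "
                      "predictors may be collinear")
    w = None if weights is None else np.asarray(weights, dtype=float)
    names = ["const"] + list(predictors)
    if np.ptp(y) == 0:
        # constant outcome: the perfect fit has intercept ln(c) and zero
        # slopes; the gamma likelihood is unbounded so information criteria
        # are degenerate
        c = float(y[0])
        zeros = pd.Series(0.0, index=names)
        coef = zeros.copy()
        coef["const"] = np.log(c)
        return CostModelFit(
            coefficients=coef, bse=zeros, pvalues=pd.Series(1.0, index=names),
            eta=pd.Series(np.log(c), index=records.index),
            mu=pd.Series(c, index=records.index),
            dispersion=0.0, loglik=float("inf"), aic=float("-inf"),
            bic=float("-inf"), nobs=len(y), predictors=list(predictors),
            outcome=outcome, y=y, weights=w, results=None)
    res = _fit_gamma_glm(y, X, w)
    k = len(names) + 1  # + dispersion
    llf = float(res.llf)
    n = len(y)
    return CostModelFit(
        coefficients=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        eta=pd.Series(np.log(res.fittedvalues), index=records.index),
        mu=pd.Series(res.fittedvalues, index=records.index),
        dispersion=float(res.scale),
        loglik=llf,
        aic=-2 * llf + 2 * k,
        bic=-2 * llf + k * np.log(n),
        nobs=n,
        predictors=list(predictors),
        outcome=outcome,
        y=y,
        weights=w,
        results=res,
    )


# ---------------------------------------------------------------------------
# ATET
# ---------------------------------------------------------------------------

def estimate_atet(fit: CostModelFit, records: pd.DataFrame, treatment: str) -> float:
    """ATET by recycled predictions over the treated subjects only.

    Each treated subject is predicted with the treatment indicator set to 1
    and to 0; the mean difference is the ATET in outcome units (US$).
    """
    if treatment not in fit.predictors:
        raise ValidationError(f"treatment {treatment!r} is not among the fitted predictors")
    treated = records[records[treatment] == 1]
    if len(treated) == 0:
        raise ValidationError("treatment group is empty")
    on = treated.copy()
    off = treated.copy()
    on[treatment] = 1
    off[treatment] = 0
    return float(np.mean(fit.predict_mu(on) - fit.predict_mu(off)))


@dataclass
class ATETResult:
    """Bootstrap ATET: point estimate, SE and confidence interval (US$)."""

    estimate: float
    bootstrap_se: float
    ci_low: float
    ci_high: float
    n_reps: int
    seed: int
    n_failed: int = 0
    ci_type: str = "normal"
    replicates: np.ndarray | None = field(repr=False, default=None)

    @property
    def ci_width(self) -> float:
        return self.ci_high - self.ci_low

    def covers(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high


def _atet_chain(y: np.ndarray, t: np.ndarray, Xg: np.ndarray, Xp: np.ndarray) -> float:
    """One pass of propensity -> weights -> weighted gamma GLM -> ATET.

    ``Xg`` is the GLM design without constant, with the treatment indicator
    in column 0; ``Xp`` the propensity design without constant.
    """
    if t.min() == t.max():
        raise ValidationError("single-class treatment in replicate")
    if np.ptp(y) == 0:
        return 0.0  # constant outcome: no effect by construction
    _, p = _propensity_probs(t, sm.add_constant(Xp, has_constant="add"))
    w = atet_weights(p, t)
    Xg_c = np.column_stack([np.ones(len(y)), t, Xg])
    res = _fit_gamma_glm(y, Xg_c, w)
    b = res.params
    treated = t == 1
    eta_off = Xg_c[treated] @ b - b[1]  # toggle treatment column off
    eta_on = eta_off + b[1]
    return float(np.mean(np.exp(eta_on) - np.exp(eta_off)))


def bootstrap_atet(records: pd.DataFrame, treatment: str, predictors: list[str],
                   propensity_covariates: list[str] | None = None,
                   n_reps: int = 1000, seed: int = 0,
                   outcome: str = "direct_cost",
                   ci_type: str = "normal", alpha: float = 0.05,
                   max_failure_rate: float = 0.10) -> ATETResult:
    """Subject-level bootstrap of the full IPTW + gamma-GLM ATET chain.

    The propensity model is refit inside every replicate so that weight
    uncertainty propagates. The default confidence interval is the normal
    approximation ``estimate ± z * SE``; ``ci_type="percentile"`` uses the
    replicate distribution instead. Replicates that fail (separation,
    non-convergence, single-class resample) are counted; more than
    ``max_failure_rate`` failures is an error.
    """
    if n_reps < 2:
        raise ValidationError("n_reps must be >= 2")
    if propensity_covariates is None:
        propensity_covariates = [c for c in predictors if c != treatment]
    glm_covs = [c for c in predictors if c != treatment]

    y = records[outcome].to_numpy(dtype=float)
    t = records[treatment].to_numpy(dtype=int)
    Xg = records[glm_covs].to_numpy(dtype=float)
    Xp = records[propensity_covariates].to_numpy(dtype=float)
    n = len(y)

    point = _atet_chain(y, t, Xg, Xp)

    rng = np.random.default_rng(seed)
    reps = np.empty(n_reps)
    failed = 0
    for b in range(n_reps):
        idx = rng.integers(0, n, n)
        try:
            reps[b] = _atet_chain(y[idx], t[idx], Xg[idx], Xp[idx])
        except (SeparationError, ConvergenceError, ValidationError, np.linalg.LinAlgError):
            reps[b] = np.nan
            failed += 1
    if failed > max_failure_rate * n_reps:
        raise ConvergenceError(
            f"{failed}/{n_reps} bootstrap replicates failed (limit {max_failure_rate:.0%})")
    good = reps[~np.isnan(reps)]
    se = float(np.std(good, ddof=1))
    z = stats.norm.ppf(1 - alpha / 2)
    if ci_type == "percentile":
        lo, hi = np.quantile(good, [alpha / 2, 1 - alpha / 2])
    elif ci_type == "normal":
        lo, hi = point - z * se, point + z * se
    else:
        raise ValueError(f"unknown ci_type {ci_type!r}")
    return ATETResult(point, se, float(lo), float(hi), n_reps, seed,
                      n_failed=failed, ci_type=ci_type, replicates=good)


# ---------------------------------------------------------------------------
# covariate selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    retained: list[str]
    frame: pd.DataFrame          # input copy plus any binarised columns
    binarised: dict[str, str]    # original name -> binarised column name


def select_covariates(records: pd.DataFrame, candidates: list[str],
                      outcome: str = "direct_cost",
                      alpha: float = 0.10) -> SelectionResult:
    """Retain candidates at p < ``alpha`` in a multivariable gamma GLM, then
    binarise continuous covariates when that does not increase the AIC.

    Backward elimination drops the least significant candidate until all
    survivors clear ``alpha``. Retained covariates with more than two levels
    are then tested one at a time in a median-split binarised form
    (``name_gt_<median>``); the split is kept iff the refit AIC does not
    increase. If everything is dropped the result is an intercept-only model
    (warned, not fatal).
    """
    if not candidates:
        raise ValidationError("candidate list is empty")
    df = records.copy()
    retained = [c for c in candidates if df[c].nunique() > 1]
    while retained:
        fit = fit_cost_glm(df, outcome, retained)
        pvals = fit.pvalues[retained]
        worst = pvals.idxmax()
        if pvals[worst] < alpha:
            break
        retained.remove(worst)
    if not retained:
        warnings.warn("all candidates dropped; intercept-only cost model")
        return SelectionResult([], df, {})

    binarised: dict[str, str] = {}
    current_aic = fit_cost_glm(df, outcome, retained).aic
    for name in list(retained):
        if df[name].nunique() <= 2:
            continue
        med = float(df[name].median())
        bname = f"{name}_gt_{med:g}"
        df[bname] = (df[name] > med).astype(int)
        trial = [bname if c == name else c for c in retained]
        if df[bname].nunique() < 2:
            df = df.drop(columns=bname)
            continue
        trial_aic = fit_cost_glm(df, outcome, trial).aic
        if trial_aic <= current_aic:
            retained = trial
            binarised[name] = bname
            current_aic = trial_aic
        else:
            df = df.drop(columns=bname)
    return SelectionResult(retained, df, binarised)
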