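"""Predicted length-of-stay (VMLOS) index derived from baseline factors.

The index is fit on the derivation sample: candidate baseline covariates are
screened by bivariate association with ln(LOS), a multivariable linear model
of ln(LOS) is pruned by backward elimination until every retained predictor
has p < 0.10, predictions are discretised at derivation-sample tertiles, and
each of the three categories (short / medium / long stay) is tagged with the
arithmetic mean *observed* LOS of its derivation subjects — those per-category
day values are what downstream code uses as predicted LOS.

The fit uses baseline covariates only; outcome-derived fields (observed LOS,
cost, palliative-care day, death) never enter the design, which is what makes
the index usable at admission.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import SchemaError, ValidationError
from .schema import ELIX_COLUMNS, prepare_model_frame

CATEGORIES = ("short", "medium", "long")

#: Default candidate predictors: the 31 condition flags plus demographics,
#: diagnosis, insurance and first-day admission type.
DEFAULT_CANDIDATES = ELIX_COLUMNS + [
    "age_years", "female",
    "race_black", "race_other",
    "ins_medicaid_none", "ins_other",
    "dx_solid_tumor", "dx_heme_tumor",
    "admitted_via_ed", "icu_day1", "surgery_day1",
]

OUTCOME_FIELDS = ("los_days", "direct_cost", "pc_day", "died_in_hospital")


@dataclass
class VMLOSModel:
    """Fitted ln(LOS) rule plus its 3-category discretisation."""

    retained_predictors: list[str]
    coefficients: dict[str, float]
    intercept: float
    cutpoints: tuple[float, float] | None
    category_los: dict[str, float]
    degenerate: bool = False
    n_derivation: int = 0

    def __post_init__(self) -> None:
        if not self.degenerate:
            los = [self.category_los[c] for c in CATEGORIES]
            if not (los[0] < los[1] < los[2]):
                raise ValidationError("category_los must be strictly increasing short < medium < long")
            if not self.cutpoints[0] < self.cutpoints[1]:
                raise ValidationError("cutpoints must be strictly ordered")

    def linear_predictor(self, records: pd.DataFrame) -> pd.Series:
        """Predicted ln(LOS) for each record."""
        if self.degenerate:
            return pd.Series(np.log(self.category_los["all"]), index=records.index)
        eta = np.full(len(records), self.intercept)
        for name in self.retained_predictors:
            if name not in records.columns:
                raise SchemaError(f"record is missing retained predictor {name!r}")
            eta = eta + self.coefficients[name] * records[name].to_numpy(dtype=float)
        return pd.Series(eta, index=records.index)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "retained_predictors": self.retained_predictors,
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "cutpoints": list(self.cutpoints) if self.cutpoints else None,
            "category_los": self.category_los,
            "degenerate": self.degenerate,
            "n_derivation": self.n_derivation,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "VMLOSModel":
        d = json.loads(Path(path).read_text())
        d["cutpoints"] = tuple(d["cutpoints"]) if d["cutpoints"] else None
        return cls(**d)


def fit_vmlos(derivation_records: pd.DataFrame,
              candidates: list[str] | None = None,
              alpha_retain: float = 0.10,
              screen_alpha: float = 0.20) -> VMLOSModel:
    """Derive the predicted-LOS index on a derivation sample.

    Parameters
    ----------
    derivation_records:
        Cohort rows with ``los_days >= 1``. Categorical expansions are added
        automatically when the raw cohort columns are present.
    candidates:
        Baseline covariate names to consider (default: condition flags plus
        demographics/admission type).
    alpha_retain:
        Multivariable retention threshold (backward elimination).
    screen_alpha:
        Liberal bivariate pre-screen threshold.

    A model with zero retained predictors degenerates to a single-category
    rule carrying the overall mean observed LOS; this is flagged, not fatal.
    """
    if len(derivation_records) == 0:
        raise ValidationError("derivation sample is empty")
    if (derivation_records["los_days"] < 1).any():
        raise ValidationError("los_days must be >= 1 in the derivation sample")

    df = derivation_records
    if candidates is None:
        if not all(c in df.columns for c in DEFAULT_CANDIDATES):
            df = prepare_model_frame(df)
        candidates = [c for c in DEFAULT_CANDIDATES if c in df.columns]
    missing = [c for c in candidates if c not in df.columns]
    if missing:
        raise SchemaError(f"derivation sample is missing candidate columns {missing}")

    y = np.log(df["los_days"].to_numpy(dtype=float))
    obs_los = df["los_days"].to_numpy(dtype=float)

    # 1) bivariate screen against ln(LOS)
    screened = []
    for name in candidates:
        x = df[name].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            continue
        res = sm.OLS(y, sm.add_constant(x)).fit()
        if res.pvalues[1] < screen_alpha:
            screened.append(name)

    # 2) multivariable backward elimination at alpha_retain
    retained = list(screened)
    while retained:
        X = sm.add_constant(df[retained].to_numpy(dtype=float))
        res = sm.OLS(y, X).fit()
        pvals = res.pvalues[1:]
        worst = int(np.argmax(pvals))
        if pvals[worst] < alpha_retain:
            break
        retained.pop(worst)

    if not retained:
        warnings.warn("no predictors retained; falling back to a single-category mean-LOS model")
        return VMLOSModel(
            retained_predictors=[], coefficients={}, intercept=float(np.mean(y)),
            cutpoints=None, category_los={"all": float(np.mean(obs_los))},
            degenerate=True, n_derivation=len(df),
        )

    X = sm.add_constant(df[retained].to_numpy(dtype=float))
    res = sm.OLS(y, X).fit()
    coef = dict(zip(retained, (float(b) for b in res.params[1:])))
    intercept = float(res.params[0])

    # 3-4) predictions and tertile cutpoints on the derivation sample
    eta = res.fittedvalues
    c1, c2 = np.quantile(eta, [1 / 3, 2 / 3])
    if not c1 < c2:  # massive ties: treat as degenerate
        warnings.warn("tertile cutpoints coincide; falling back to a single-category model")
        return VMLOSModel(
            retained_predictors=[], coefficients={}, intercept=float(np.mean(y)),
            cutpoints=None, category_los={"all": float(np.mean(obs_los))},
            degenerate=True, n_derivation=len(df),
        )

    # 5) per-category mean observed LOS (ties at a cutpoint go to the lower
    # category). A guard enforces strict ordering against tie pathologies.
    cat = np.where(eta <= c1, 0, np.where(eta <= c2, 1, 2))
    means = [float(obs_los[cat == k].mean()) if (cat == k).any() else float("nan") for k in range(3)]
    means = [float(v) for v in np.maximum.accumulate(means)]
    for k in range(1, 3):
        if means[k] <= means[k - 1]:
            means[k] = means[k - 1] + 1e-9
    category_los = dict(zip(CATEGORIES, means))

    return VMLOSModel(
        retained_predictors=retained, coefficients=coef, intercept=intercept,
        cutpoints=(float(c1), float(c2)), category_los=category_los,
        n_derivation=len(df),
    )


def predict_vmlos(model: VMLOSModel, records: pd.DataFrame) -> pd.DataFrame:
    """Categorise records and return their predicted LOS in days.

    Returns a DataFrame with ``vmlos_category`` and ``vmlos_pred_days``
    columns aligned to ``records``. A score exactly at a cutpoint is assigned
    to the lower (shorter-stay) category.
    """
    if model.degenerate:
        return pd.DataFrame({
            "vmlos_category": pd.Series("all", index=records.index),
            "vmlos_pred_days": pd.Series(model.category_los["all"], index=records.index),
        })
    eta = model.linear_predictor(records)
    c1, c2 = model.cutpoints
    cat = np.where(eta <= c1, "short", np.where(eta <= c2, "medium", "long"))
    days = np.vectorize(model.category_los.__getitem__)(cat).astype(float)
    return pd.DataFrame(
        {"vmlos_category": cat, "vmlos_pred_days": days}, index=records.index
    )
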