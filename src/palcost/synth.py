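"""Seed-reproducible synthetic admission cohorts with known counterfactuals.

The generator emulates the structure the cost analysis assumes:

* right-skewed, gamma-like total direct costs built up from per-day gamma
  draws whose expected value decays geometrically over the stay (costs are
  accumulated disproportionately early in an admission);
* length of stay log-normal in baseline covariates, rounded up to whole days;
* a latent severity factor that raises condition-flag prevalences, LOS and
  daily cost — the "complexity" that a predicted-LOS index can proxy;
* palliative-care receipt selected on *observed* baseline covariates
  (confounding the pipeline must remove), with an early-skewed engagement
  day, and a multiplicative effect on daily cost that applies only to days
  strictly after first engagement — so earlier engagement has more cost left
  to change.

Both potential outcomes (cost with and without the palliative-care
multiplier) are drawn from the same per-day cost realisations and returned
as :class:`GeneratorTruth`, so pipeline estimates can be checked against the
generator's own average treatment effect on the treated.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import schema, scores
from .exceptions import ParameterError, SchemaError
from .schema import (
    CCI_COLUMNS,
    COHORT_COLUMNS,
    ELIX_COLUMNS,
    FLAG_COLUMNS,
    LIFE_LIMITING_COLUMNS,
)

# Log-scale effects applied both to expected daily cost and to ln(LOS).
DEFAULT_COVARIATE_EFFECTS: dict[str, float] = {
    "severity": 0.30,        # latent complexity, N(0,1)
    "icu_day1": 0.35,
    "surgery_day1": 0.20,
    "dx_solid_tumor": 0.12,
    "dx_heme_tumor": 0.18,
    "charlson_score": 0.05,  # per Charlson point
    "age_decades_c": 0.03,   # per decade above 60
}

# Log-odds of palliative-care receipt. Selection acts on observed baseline
# covariates only by default; add a "severity" entry to study unobserved
# selection.
DEFAULT_PC_SELECTION_EFFECTS: dict[str, float] = {
    "intercept": -2.8,
    "charlson_score": 0.12,
    "dx_solid_tumor": 0.9,
    "icu_day1": -0.5,
    "surgery_day1": -0.8,
    "age_over_75": 0.35,
    "admitted_via_ed": 0.25,
}

# (base prevalence, log-odds slope on latent severity) for each Elixhauser
# condition; tuned to a seriously-ill tertiary-center case mix so that the
# van Walraven score spans the eligibility floors used in sample definition.
ELIX_GENERATION: dict[str, tuple[float, float]] = {
    "congestive_heart_failure": (0.25, 0.6),
    "cardiac_arrhythmias": (0.30, 0.5),
    "valvular_disease": (0.10, 0.3),
    "pulmonary_circulation_disorders": (0.08, 0.5),
    "peripheral_vascular_disorders": (0.10, 0.4),
    "hypertension_uncomplicated": (0.45, 0.2),
    "hypertension_complicated": (0.10, 0.4),
    "paralysis": (0.05, 0.5),
    "other_neurological_disorders": (0.12, 0.5),
    "chronic_pulmonary_disease": (0.25, 0.4),
    "diabetes_uncomplicated": (0.20, 0.2),
    "diabetes_complicated": (0.10, 0.4),
    "hypothyroidism": (0.10, 0.1),
    "renal_failure": (0.25, 0.6),
    "liver_disease": (0.10, 0.6),
    "peptic_ulcer_disease": (0.03, 0.3),
    "aids_hiv": (0.02, 0.2),
    "lymphoma": (0.05, 0.4),
    "metastatic_cancer": (0.02, 0.4),   # mostly driven by primary diagnosis
    "solid_tumor_without_metastasis": (0.02, 0.3),
    "rheumatoid_arthritis": (0.04, 0.2),
    "coagulopathy": (0.15, 0.7),
    "obesity": (0.12, 0.1),
    "weight_loss": (0.25, 0.7),
    "fluid_electrolyte_disorders": (0.45, 0.7),
    "blood_loss_anemia": (0.08, 0.4),
    "deficiency_anemia": (0.20, 0.4),
    "alcohol_abuse": (0.08, 0.3),
    "drug_abuse": (0.08, 0.2),
    "psychoses": (0.05, 0.2),
    "depression": (0.15, 0.2),
}


@dataclass
class GeneratorParams:
    """Tunable structure of the synthetic cohort.

    ``pc_effect`` multiplies expected daily cost on days strictly after first
    palliative-care engagement (1.0 = no effect). ``pc_timing_skew`` > 0 sets
    the geometric decay rate exp(-skew) of the engagement-day distribution:
    larger values skew engagement earlier. ``covariate_effects`` apply on the
    log scale to both expected daily cost and ln(LOS).
    """

    n_subjects: int = 2674
    seed: int = 0
    baseline_daily_cost: float = 1900.0
    cost_shape: float = 1.5
    cost_decay: float = 0.92
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    pc_effect: float = 0.7
    pc_selection_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PC_SELECTION_EFFECTS))
    pc_timing_skew: float = 0.35
    mortality_base_rate: float = 0.25
    repeat_admission_rate: float = 0.20
    los_intercept: float = 1.55
    los_sigma: float = 0.45
    max_los: int = 60

    def validate(self) -> "GeneratorParams":
        if self.n_subjects < 0:
            raise ParameterError("n_subjects must be >= 0")
        if self.cost_shape <= 0:
            raise ParameterError("cost_shape must be positive")
        if self.pc_effect <= 0:
            raise ParameterError("pc_effect must be positive")
        if not 0 < self.cost_decay <= 1:
            raise ParameterError("cost_decay must be in (0, 1]")
        if self.pc_timing_skew <= 0:
            raise ParameterError("pc_timing_skew must be positive")
        if not 0 < self.mortality_base_rate < 1:
            raise ParameterError("mortality_base_rate must be in (0, 1)")
        if self.baseline_daily_cost <= 0:
            raise ParameterError("baseline_daily_cost must be positive")
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariate_effects"] = dict(self.covariate_effects)
        d["pc_selection_effects"] = dict(self.pc_selection_effects)
        return d


@dataclass
class GeneratorTruth:
    """Per-subject potential outcomes and the generator's own ATET.

    ``y0``/``y1`` are total direct cost without and with the palliative-care
    multiplier applied from each subject's realised engagement day (equal for
    subjects who never engage). ``true_atet`` averages ``y1 - y0`` over the
    realised treatment group under the default fixed-day rule (engagement
    within 3 days); NaN when that group is empty.
    """

    params: GeneratorParams
    y0: np.ndarray
    y1: np.ndarray
    pc_received: np.ndarray
    pc_day: np.ndarray  # float array, NaN where no engagement
    true_atet: float

    def atet_for(self, treated_mask: np.ndarray) -> float:
        """Average y1 - y0 over an arbitrary treated subset."""
        treated_mask = np.asarray(treated_mask, dtype=bool)
        if treated_mask.sum() == 0:
            return float("nan")
        return float(np.mean(self.y1[treated_mask] - self.y0[treated_mask]))


def _features(df: pd.DataFrame, severity: np.ndarray, name: str) -> np.ndarray:
    if name == "severity":
        return severity
    if name == "age_decades_c":
        return (df["age_years"].to_numpy() - 60.0) / 10.0
    if name == "age_over_75":
        return (df["age_years"].to_numpy() > 75).astype(float)
    if name == "intercept":
        return np.ones(len(df))
    if name in df.columns:
        return df[name].to_numpy(dtype=float)
    raise ParameterError(f"unknown covariate {name!r} in generator effects")


def generate_cohort(params: GeneratorParams) -> tuple[pd.DataFrame, GeneratorTruth]:
    """Draw a cohort of admission records plus its generator truth.

    Identical ``params`` (including ``seed``) yield identical tables.
    """
    params.validate()
    n = params.n_subjects
    rng = np.random.default_rng(params.seed)
    if n == 0:
        empty = schema.empty_cohort()
        truth = GeneratorTruth(params, np.empty(0), np.empty(0),
                               np.empty(0, bool), np.empty(0), float("nan"))
        return empty, truth

    df = pd.DataFrame(index=pd.RangeIndex(n))
    df["patient_id"] = [f"P{i:06d}" for i in range(n)]
    df["admission_index"] = 1
    df["age_years"] = np.round(np.clip(rng.normal(62.0, 15.0, n), 18.0, 100.0), 1)
    df["female"] = (rng.random(n) < 0.5).astype(int)
    df["race"] = rng.choice(schema.RACE_LEVELS, size=n, p=[0.55, 0.35, 0.10])
    df["insurance"] = rng.choice(schema.INSURANCE_LEVELS, size=n, p=[0.45, 0.35, 0.20])
    df["primary_dx"] = rng.choice(schema.DX_LEVELS, size=n, p=[0.60, 0.35, 0.05])

    severity = rng.normal(0.0, 1.0, n)
    df["admitted_via_ed"] = (rng.random(n) < expit(0.2 + 0.5 * severity)).astype(int)
    df["icu_day1"] = (rng.random(n) < expit(-1.5 + 0.8 * severity)).astype(int)
    df["surgery_day1"] = (rng.random(n) < expit(-2.0 - 0.2 * severity)).astype(int)

    solid = df["primary_dx"].to_numpy() == "solid_tumor"
    heme = df["primary_dx"].to_numpy() == "heme_tumor"
    df["dx_solid_tumor"] = solid.astype(int)
    df["dx_heme_tumor"] = heme.astype(int)

    for cond, (base, slope) in ELIX_GENERATION.items():
        p = expit(logit(base) + slope * severity)
        df["elix_" + cond] = (rng.random(n) < p).astype(int)
    # tie tumour conditions to the primary diagnosis
    mets = (solid & (rng.random(n) < 0.55)) | (rng.random(n) < 0.02)
    df["elix_metastatic_cancer"] = (df["elix_metastatic_cancer"].astype(bool) | mets).astype(int)
    tum = solid & ~mets & (rng.random(n) < 0.70)
    df["elix_solid_tumor_without_metastasis"] = (
        df["elix_solid_tumor_without_metastasis"].astype(bool) | tum).astype(int)
    df["elix_lymphoma"] = (df["elix_lymphoma"].astype(bool) | (heme & (rng.random(n) < 0.5))).astype(int)

    # Charlson flags: shared conditions mirror the Elixhauser draw; the rest
    # are independent severity-linked draws.
    e = lambda c: df["elix_" + c].astype(bool).to_numpy()
    liver_split = rng.random(n) < 0.7
    df["cci_congestive_heart_failure"] = e("congestive_heart_failure").astype(int)
    df["cci_chronic_pulmonary_disease"] = e("chronic_pulmonary_disease").astype(int)
    df["cci_peripheral_vascular_disease"] = e("peripheral_vascular_disorders").astype(int)
    df["cci_peptic_ulcer_disease"] = e("peptic_ulcer_disease").astype(int)
    df["cci_rheumatologic_disease"] = e("rheumatoid_arthritis").astype(int)
    df["cci_hemiplegia_or_paraplegia"] = e("paralysis").astype(int)
    df["cci_renal_disease"] = e("renal_failure").astype(int)
    df["cci_aids_hiv"] = e("aids_hiv").astype(int)
    df["cci_metastatic_solid_tumor"] = e("metastatic_cancer").astype(int)
    df["cci_lymphoma"] = e("lymphoma").astype(int)
    df["cci_mild_liver_disease"] = (e("liver_disease") & liver_split).astype(int)
    df["cci_moderate_severe_liver_disease"] = (e("liver_disease") & ~liver_split).astype(int)
    df["cci_diabetes_without_complications"] = e("diabetes_uncomplicated").astype(int)
    df["cci_diabetes_with_complications"] = e("diabetes_complicated").astype(int)
    df["cci_any_malignancy"] = (
        solid | heme | e("metastatic_cancer") | e("solid_tumor_without_metastasis")).astype(int)
    df["cci_leukemia"] = (heme & (rng.random(n) < 0.5)).astype(int)
    df["cci_myocardial_infarction"] = (rng.random(n) < expit(logit(0.12) + 0.4 * severity)).astype(int)
    df["cci_cerebrovascular_disease"] = (rng.random(n) < expit(logit(0.10) + 0.4 * severity)).astype(int)
    age = df["age_years"].to_numpy()
    df["cci_dementia"] = (rng.random(n) < expit(-3.2 + 0.05 * (age - 60.0))).astype(int)

    # life-limiting diagnosis flags
    df["ll_advanced_cancer"] = (e("metastatic_cancer") | ((solid | heme) & (rng.random(n) < 0.5))).astype(int)
    df["ll_heart_failure"] = e("congestive_heart_failure").astype(int)
    df["ll_serious_respiratory"] = (e("chronic_pulmonary_disease") & (rng.random(n) < 0.5)).astype(int)
    df["ll_advanced_liver"] = df["cci_moderate_severe_liver_disease"].to_numpy()
    df["ll_advanced_kidney"] = (e("renal_failure") & (rng.random(n) < 0.6)).astype(int)
    df["ll_dementia"] = df["cci_dementia"].to_numpy()
    df["ll_aids_hiv"] = e("aids_hiv").astype(int)

    df["charlson_score"] = scores.charlson_score(df)
    df["vw_score"] = scores.van_walraven_score(df)

    # linear predictor shared by ln(LOS) and log expected daily cost
    eta = np.zeros(n)
    for name, beta in params.covariate_effects.items():
        eta += beta * _features(df, severity, name)
    ln_los = params.los_intercept + eta + rng.normal(0.0, params.los_sigma, n)
    los = np.clip(np.ceil(np.exp(ln_los)), 1, params.max_los).astype(int)
    df["los_days"] = los

    # palliative-care receipt and engagement day
    sel = np.zeros(n)
    for name, beta in params.pc_selection_effects.items():
        sel += beta * _features(df, severity, name)
    intent = rng.random(n) < expit(sel)
    # Engagement day: geometric-tailed with ratio r = exp(-skew), split into an
    # early phase (days 1-3) and a late phase (day 4 onward, truncated at
    # discharge). Late-intent subjects discharged before day 4 never engage —
    # the referral does not happen — rather than being forced into an early
    # engagement. This keeps early-engagement status independent of the
    # length-of-stay noise given covariates, so timing itself does not
    # confound the default treatment rule.
    r = float(np.exp(-params.pc_timing_skew))
    early = rng.random(n) < (1.0 - r ** 3)
    u = rng.random(n)

    def _trunc_geom(u_, m_):
        # inverse CDF of P(k) ∝ r^(k-1) on 1..m
        with np.errstate(divide="ignore", invalid="ignore"):
            k = np.ceil(np.log1p(-u_ * (1.0 - r ** m_)) / np.log(r))
        return np.maximum(1, np.where(np.isfinite(k), k, 1)).astype(int)

    day_early = np.minimum(_trunc_geom(u, np.full(n, 3)), los)
    can_late = los >= 4
    day_late = 3 + _trunc_geom(u, np.maximum(los - 3, 1))
    day = np.where(early, day_early, np.minimum(day_late, los))
    received = intent & (early | can_late)
    pc_day = np.where(received, day, np.nan)
    pc_col = pd.Series(day, index=df.index, dtype="Int64")
    pc_col[~received] = pd.NA
    df["pc_day"] = pc_col

    # per-day gamma cost draws with geometric decay of the expected value
    daily_mean0 = params.baseline_daily_cost * np.exp(eta)
    idx = np.repeat(np.arange(n), los)
    total_days = int(los.sum())
    starts = np.concatenate([[0], np.cumsum(los)[:-1]])
    day0 = np.arange(total_days) - np.repeat(starts, los)  # 0-based day within stay
    m = daily_mean0[idx] * params.cost_decay ** day0
    draws = rng.gamma(params.cost_shape, m / params.cost_shape)
    y0 = np.bincount(idx, weights=draws, minlength=n)
    after = received[idx] & ((day0 + 1) > np.where(received, day, 10 ** 9)[idx])
    post = np.bincount(idx, weights=draws * after, minlength=n)
    y1 = y0 - (1.0 - params.pc_effect) * post
    df["direct_cost"] = np.where(received, y1, y0)

    # in-hospital mortality: logistic in the van Walraven score, anchored so
    # the base rate applies at the analytic-sample eligibility floor (20)
    mort = expit(logit(params.mortality_base_rate) + 0.09 * (df["vw_score"].to_numpy() - 20.0))
    df["died_in_hospital"] = (rng.random(n) < mort).astype(int)
    df["transplant"] = (rng.random(n) < 0.02).astype(int)
    df["trauma"] = (rng.random(n) < 0.02).astype(int)

    # mark a share of records as second admissions of earlier patients
    k = min(int(round(params.repeat_admission_rate * n)), n // 3)
    if k > 0:
        repeat_rows = np.arange(n - k, n)
        donors = rng.choice(n - k, size=k, replace=False)
        for col in ["patient_id", "age_years", "female", "race", "insurance"]:
            df.loc[repeat_rows, col] = df[col].to_numpy()[donors]
        df.loc[repeat_rows, "admission_index"] = 2

    df = df.drop(columns=["dx_solid_tumor", "dx_heme_tumor", "charlson_score", "vw_score"])
    df = df[COHORT_COLUMNS]
    schema.validate_cohort(df)

    t1_default = received & (day <= 3)
    true_atet = float(np.mean(y1[t1_default] - y0[t1_default])) if t1_default.any() else float("nan")
    truth = GeneratorTruth(params, y0, y1, received, pc_day, true_atet)
    return df, truth


def write_cohort(records: pd.DataFrame, path: str | Path) -> None:
    """Write a validated cohort table to CSV (empty pc_day = no engagement)."""
    schema.validate_cohort(records)
    records.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV written by :func:`write_cohort`."""
    try:
        df = pd.read_csv(path, dtype={"patient_id": str})
    except (ValueError, OSError) as exc:
        raise SchemaError(f"cannot read cohort file {path}: {exc}") from exc
    for col in COHORT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"cohort file {path} is missing required column {col!r}")
    df["pc_day"] = df["pc_day"].astype("Int64")
    df["los_days"] = df["los_days"].astype("int64")
    df["admission_index"] = df["admission_index"].astype("int64")
    for col in FLAG_COLUMNS:
        df[col] = df[col].astype(int)
    df = df[COHORT_COLUMNS]
    schema.validate_cohort(df)
    return df


def write_truth(truth: GeneratorTruth, path: str | Path) -> None:
    """JSON sidecar with the generator parameters and true ATET."""
    payload = {
        "params": truth.params.to_dict(),
        "true_atet": None if np.isnan(truth.true_atet) else truth.true_atet,
        "n_pc_received": int(truth.pc_received.sum()),
    }
    Path(path).write_text(json.dumps(payload, indent=2))
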