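"""Cohort table schema: column names, categorical levels, validation.

A cohort is a pandas DataFrame with one row per hospital admission. Condition
flags use the canonical published condition labels, prefixed ``elix_`` for the
31 Elixhauser conditions and ``cci_`` for the 19 Charlson conditions so the
two indices' overlapping condition names cannot collide.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError

ELIXHAUSER_CONDITIONS = [
    "congestive_heart_failure",
    "cardiac_arrhythmias",
    "valvular_disease",
    "pulmonary_circulation_disorders",
    "peripheral_vascular_disorders",
    "hypertension_uncomplicated",
    "hypertension_complicated",
    "paralysis",
    "other_neurological_disorders",
    "chronic_pulmonary_disease",
    "diabetes_uncomplicated",
    "diabetes_complicated",
    "hypothyroidism",
    "renal_failure",
    "liver_disease",
    "peptic_ulcer_disease",
    "aids_hiv",
    "lymphoma",
    "metastatic_cancer",
    "solid_tumor_without_metastasis",
    "rheumatoid_arthritis",
    "coagulopathy",
    "obesity",
    "weight_loss",
    "fluid_electrolyte_disorders",
    "blood_loss_anemia",
    "deficiency_anemia",
    "alcohol_abuse",
    "drug_abuse",
    "psychoses",
    "depression",
]

CHARLSON_CONDITIONS = [
    "myocardial_infarction",
    "congestive_heart_failure",
    "peripheral_vascular_disease",
    "cerebrovascular_disease",
    "dementia",
    "chronic_pulmonary_disease",
    "rheumatologic_disease",
    "peptic_ulcer_disease",
    "mild_liver_disease",
    "diabetes_without_complications",
    "diabetes_with_complications",
    "hemiplegia_or_paraplegia",
    "renal_disease",
    "any_malignancy",
    "leukemia",
    "lymphoma",
    "moderate_severe_liver_disease",
    "metastatic_solid_tumor",
    "aids_hiv",
]

ELIX_COLUMNS = ["elix_" + c for c in ELIXHAUSER_CONDITIONS]
CCI_COLUMNS = ["cci_" + c for c in CHARLSON_CONDITIONS]

# The seven life-limiting diagnoses that define cohort eligibility.
LIFE_LIMITING_COLUMNS = [
    "ll_advanced_cancer",
    "ll_heart_failure",
    "ll_serious_respiratory",
    "ll_advanced_liver",
    "ll_advanced_kidney",
    "ll_dementia",
    "ll_aids_hiv",
]

RACE_LEVELS = ["white", "black", "other"]
INSURANCE_LEVELS = ["medicare", "medicaid_none", "other"]
DX_LEVELS = ["noncancer", "solid_tumor", "heme_tumor"]

FLAG_COLUMNS = (
    ["female", "admitted_via_ed", "icu_day1", "surgery_day1",
     "died_in_hospital", "transplant", "trauma"]
    + LIFE_LIMITING_COLUMNS + ELIX_COLUMNS + CCI_COLUMNS
)

COHORT_COLUMNS = (
    ["patient_id", "admission_index", "age_years", "female", "race",
     "insurance", "admitted_via_ed", "icu_day1", "surgery_day1", "primary_dx"]
    + LIFE_LIMITING_COLUMNS
    + ELIX_COLUMNS
    + CCI_COLUMNS
    + ["los_days", "pc_day", "direct_cost", "died_in_hospital",
       "transplant", "trauma"]
)

# Baseline covariate set used in the cost and propensity models (the standard
# case-mix adjusters: age band, sex, race, first-day acuity, route of
# admission, primary diagnosis, Charlson index).
BASE_COVARIATES = [
    "age_over_75",
    "female",
    "race_white",
    "surgery_day1",
    "icu_day1",
    "admitted_via_ed",
    "dx_solid_tumor",
    "dx_heme_tumor",
    "charlson_score",
]


def validate_cohort(records: pd.DataFrame) -> pd.DataFrame:
    """Check schema completeness and record-level invariants.

    Raises
    ------
    SchemaError
        If a required column is absent (the message names the column).
    ValidationError
        If ``los_days < 1``, ``direct_cost <= 0``, ``age_years <= 0`` or a
        present ``pc_day`` falls outside ``[1, los_days]``.
    """
    for col in COHORT_COLUMNS:
        if col not in records.columns:
            raise SchemaError(f"cohort table is missing required column {col!r}")
    if len(records) == 0:
        return records
    if (records["los_days"] < 1).any():
        raise ValidationError("los_days must be >= 1 for every admission")
    if (records["direct_cost"] <= 0).any():
        raise ValidationError("direct_cost must be strictly positive")
    if (records["age_years"] <= 0).any():
        raise ValidationError("age_years must be strictly positive")
    pc = records["pc_day"]
    present = pc.notna()
    if present.any():
        bad = present & ((pc < 1) | (pc > records["los_days"]))
        if bad.any():
            i = records.index[bad][0]
            raise ValidationError(
                f"admission {i!r}: pc_day={pc.loc[i]} outside [1, los_days={records['los_days'].loc[i]}]"
            )
    return records


def prepare_model_frame(records: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with derived modelling columns added.

    Adds indicator expansions of the categorical fields (reference levels:
    white race, medicare insurance, noncancer diagnosis), the ``age_over_75``
    band used in the balance table, and the two comorbidity scores if the flag
    columns are present.
    """
    from . import scores  # local import to avoid a cycle

    df = records.copy()
    df["age_over_75"] = (df["age_years"] > 75).astype(int)
    for lev in RACE_LEVELS:
        df[f"race_{lev}"] = (df["race"] == lev).astype(int)
    for lev in INSURANCE_LEVELS[1:]:
        df[f"ins_{lev}"] = (df["insurance"] == lev).astype(int)
    df["dx_solid_tumor"] = (df["primary_dx"] == "solid_tumor").astype(int)
    df["dx_heme_tumor"] = (df["primary_dx"] == "heme_tumor").astype(int)
    if all(c in df.columns for c in ELIX_COLUMNS) and "vw_score" not in df.columns:
        df["vw_score"] = scores.van_walraven_score(df[ELIX_COLUMNS])
    if all(c in df.columns for c in CCI_COLUMNS) and "charlson_score" not in df.columns:
        df["charlson_score"] = scores.charlson_score(df[CCI_COLUMNS])
    for col in FLAG_COLUMNS:
        if col in df.columns:
            df[col] = df[col].astype(int)
    return df


def empty_cohort() -> pd.DataFrame:
    """An empty cohort table with the full schema."""
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in COHORT_COLUMNS})
    for c in ["admission_index", "los_days"]:
        df[c] = df[c].astype("int64")
    for c in ["age_years", "direct_cost"]:
        df[c] = df[c].astype(float)
    df["pc_day"] = df["pc_day"].astype("Int64")
    for c in FLAG_COLUMNS:
        df[c] = df[c].astype(int)
    return df
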