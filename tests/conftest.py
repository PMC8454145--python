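import numpy as np
import pandas as pd
import pytest

import palcost
from palcost import schema, treat
from palcost.schema import COHORT_COLUMNS, FLAG_COLUMNS


@pytest.fixture(scope="session")
def cohort300():
    """Small generated cohort with its truth (shared, read-only)."""
    return palcost.generate_cohort(palcost.GeneratorParams(n_subjects=300, seed=42))


@pytest.fixture(scope="session")
def model_frame_2000():
    """Confounded cohort of unique patients, prepared for modelling."""
    df, truth = palcost.generate_cohort(
        palcost.GeneratorParams(n_subjects=2000, seed=7, repeat_admission_rate=0.0))
    mf = schema.prepare_model_frame(df)
    mf["t1"] = treat.assign_t1_cohort(mf).assignment
    return mf, truth


def make_record(patient_id="P0", admission_index=1, age_years=70.0,
                los_days=5, pc_day=None, direct_cost=10_000.0,
                elix=(), cci=(), ll=(), **overrides) -> dict:
    """One full-schema admission row; condition flags given by name."""
    row = {c: 0 for c in COHORT_COLUMNS}
    row.update(patient_id=patient_id, admission_index=admission_index,
               age_years=age_years, race="white", insurance="medicare",
               primary_dx="noncancer", los_days=los_days,
               pc_day=pc_day, direct_cost=direct_cost)
    for c in elix:
        row["elix_" + c] = 1
    for c in cci:
        row["cci_" + c] = 1
    for c in ll:
        row["ll_" + c] = 1
    row.update(overrides)
    return row


def records_frame(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    df["pc_day"] = df["pc_day"].astype("Int64")
    for c in FLAG_COLUMNS:
        df[c] = df[c].astype(int)
    return df
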