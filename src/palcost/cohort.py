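"""Eligibility partition: analytic vs derivation samples.

The analytic sample contains unique patients with a terminal illness and poor
prognosis: first admissions carrying at least one of the seven life-limiting
diagnosis flags, a van Walraven score at or above the analytic floor
(default 20), not transplant/trauma admissions, and aged 18 or over. The
derivation sample — used only to fit the predicted-LOS index — relaxes to a
lower van Walraven floor (default 13) and allows repeat admissions, but
never admissions of patients already in the analytic sample. Transplant,
trauma and under-18 admissions are excluded from both samples.

Every admission lands in exactly one of: analytic, derivation, excluded
(with a reason code).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable

import pandas as pd

from . import scores
from .exceptions import ValidationError
from .schema import LIFE_LIMITING_COLUMNS

EXCLUSION_REASONS = (
    "no_life_limiting_dx",
    "below_vw_floor",
    "repeat_analytic_admission",
    "transplant",
    "trauma",
    "under_18",
)


@dataclass
class CohortPartition:
    """Disjoint, exhaustive assignment of admissions (keyed by row index)."""

    analytic_ids: set
    derivation_ids: set
    excluded: dict[Hashable, str]

    def counts(self) -> dict[str, int]:
        out = {"analytic": len(self.analytic_ids), "derivation": len(self.derivation_ids)}
        for reason in EXCLUSION_REASONS:
            out["excluded_" + reason] = sum(1 for r in self.excluded.values() if r == reason)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [(i, "analytic", "") for i in self.analytic_ids]
        rows += [(i, "derivation", "") for i in self.derivation_ids]
        rows += [(i, "excluded", r) for i, r in self.excluded.items()]
        df = pd.DataFrame(rows, columns=["admission_id", "assignment", "reason"])
        return df.sort_values("admission_id").reset_index(drop=True)


def partition(records: pd.DataFrame,
              vw_analytic_floor: int = 20,
              vw_derivation_floor: int = 13) -> CohortPartition:
    """Assign every admission to analytic, derivation or excluded.

    ``records`` rows are identified by their DataFrame index. A patient's
    first admission is the one with the smallest ``admission_index``.
    Patients whose first admission fails only the analytic van Walraven floor
    remain derivation-eligible on any admission.
    """
    if vw_derivation_floor > vw_analytic_floor:
        raise ValueError("vw_derivation_floor must not exceed vw_analytic_floor")
    if (records["age_years"] <= 0).any():
        raise ValidationError("age_years must be strictly positive")
    if len(records) == 0:
        return CohortPartition(set(), set(), {})

    vw = records["vw_score"] if "vw_score" in records.columns else scores.van_walraven_score(records)
    has_ll = records[LIFE_LIMITING_COLUMNS].astype(bool).any(axis=1)
    under_18 = records["age_years"] < 18
    transplant = records["transplant"].astype(bool)
    trauma = records["trauma"].astype(bool)
    hard_excluded = under_18 | transplant | trauma

    first_idx = records.groupby("patient_id")["admission_index"].idxmin()
    is_first = records.index.isin(first_idx.values)

    analytic_mask = (
        is_first & has_ll & (vw >= vw_analytic_floor) & ~hard_excluded
    )
    analytic_patients = set(records.loc[analytic_mask, "patient_id"])

    of_analytic_patient = records["patient_id"].isin(analytic_patients)
    repeat_analytic = of_analytic_patient & ~analytic_mask & ~hard_excluded

    derivation_mask = (
        ~of_analytic_patient & has_ll & (vw >= vw_derivation_floor) & ~hard_excluded
    )

    excluded: dict[Hashable, str] = {}
    for i in records.index:
        if analytic_mask.loc[i] or derivation_mask.loc[i]:
            continue
        if under_18.loc[i]:
            excluded[i] = "under_18"
        elif transplant.loc[i]:
            excluded[i] = "transplant"
        elif trauma.loc[i]:
            excluded[i] = "trauma"
        elif repeat_analytic.loc[i]:
            excluded[i] = "repeat_analytic_admission"
        elif not has_ll.loc[i]:
            excluded[i] = "no_life_limiting_dx"
        else:
            excluded[i] = "below_vw_floor"

    return CohortPartition(
        analytic_ids=set(records.index[analytic_mask]),
        derivation_ids=set(records.index[derivation_mask]),
        excluded=excluded,
    )
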