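"""Binary treatment variables defined by palliative-care timing.

Two rules, both inclusive at the boundary and both keeping late recipients in
the comparison group (never dropped):

* ``t1`` — fixed-day rule: treated iff first engagement occurred within ``d``
  days of admission (default 3).
* ``t2`` — fraction-of-predicted-LOS rule: treated iff the engagement day is
  within a fraction (default 1/3) of the subject's predicted LOS. The ratio
  is compared with exact rational arithmetic so a day-3 engagement against a
  predicted 9-day stay sits exactly on the boundary and is treated.

Subjects with no engagement are always in the comparison group.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ValidationError

DEFAULT_FRACTION = Fraction(1, 3)


def _is_absent(pc_day) -> bool:
    return pc_day is None or (isinstance(pc_day, float) and np.isnan(pc_day)) or pc_day is pd.NA


def assign_t1(pc_day, d: int = 3) -> int:
    """Fixed-day rule: 1 iff engagement occurred and ``pc_day <= d``."""
    if d < 1:
        raise ValidationError("d must be >= 1")
    if _is_absent(pc_day):
        return 0
    if pc_day < 1:
        raise ValidationError(f"pc_day must be >= 1, got {pc_day}")
    return int(pc_day <= d)


def assign_t2(pc_day, predicted_los, fraction: Fraction | float = DEFAULT_FRACTION) -> int:
    """Fraction-of-predicted-LOS rule: 1 iff ``pc_day / predicted_los <= fraction``.

    ``fraction`` may be a :class:`~fractions.Fraction` (exact, the default
    1/3) or a float (converted exactly from its binary representation).
    """
    frac = Fraction(fraction)
    if not 0 < frac <= 1:
        raise ValidationError("fraction must be in (0, 1]")
    if _is_absent(pc_day):
        return 0
    if pc_day < 1:
        raise ValidationError(f"pc_day must be >= 1, got {pc_day}")
    los = Fraction(float(predicted_los)) if not isinstance(predicted_los, Fraction) else predicted_los
    if los <= 0:
        raise ValidationError(f"predicted_los must be positive, got {predicted_los}")
    return int(Fraction(int(pc_day)) / los <= frac)


@dataclass
class TreatmentAssignment:
    """Per-subject 0/1 assignment under a named timing rule."""

    rule: str                    # "t1" or "t2"
    params: Mapping[str, object]
    assignment: pd.Series        # index = admission ids, values in {0, 1}

    @property
    def treated_ids(self) -> set:
        return set(self.assignment.index[self.assignment == 1])

    @property
    def n_treated(self) -> int:
        return int(self.assignment.sum())


def assign_t1_cohort(records: pd.DataFrame, d: int = 3) -> TreatmentAssignment:
    """Apply the fixed-day rule to every admission in a cohort table."""
    vals = pd.Series(
        [assign_t1(pc, d) for pc in records["pc_day"]],
        index=records.index, dtype=int,
    )
    return TreatmentAssignment("t1", {"d_threshold": d}, vals)


def assign_t2_cohort(records: pd.DataFrame, predicted_los: pd.Series,
                     fraction: Fraction | float = DEFAULT_FRACTION) -> TreatmentAssignment:
    """Apply the fraction-of-predicted-LOS rule using per-subject predicted LOS."""
    if not records.index.equals(predicted_los.index):
        raise ValidationError("predicted_los index must match the cohort index")
    vals = pd.Series(
        [assign_t2(pc, los, fraction) for pc, los in zip(records["pc_day"], predicted_los)],
        index=records.index, dtype=int,
    )
    return TreatmentAssignment("t2", {"fraction": str(Fraction(fraction))}, vals)


@dataclass
class Concurrence:
    n_both: int
    n_only_1: int
    n_only_2: int
    percent_overlap: int  # n_both / |treatment group of a2|, integer percent


def concurrence(a1: TreatmentAssignment, a2: TreatmentAssignment) -> Concurrence:
    """Joint treatment-group membership of two assignments on the same subjects."""
    if set(a1.assignment.index) != set(a2.assignment.index):
        raise ValidationError("assignments cover different subject sets")
    g1, g2 = a1.treated_ids, a2.treated_ids
    both = len(g1 & g2)
    pct = int(round(100.0 * both / len(g2))) if g2 else 0
    return Concurrence(both, len(g1 - g2), len(g2 - g1), pct)
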