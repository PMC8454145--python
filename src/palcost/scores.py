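"""Published comorbidity indices: van Walraven/Elixhauser and Charlson.

Both indices are integer sums of published condition weights over binary
condition flags. The weights ship as packaged CSV files (condition, weight,
source) rather than being hard-coded: the van Walraven weighting of the 31
Elixhauser conditions predicts in-hospital mortality; the Charlson
Comorbidity Index (CCI) weights 19 conditions as a prognostic score.

Age adjustment of the Charlson index is intentionally not applied: age enters
the cost and propensity models as its own covariate.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DimensionError
from .schema import CCI_COLUMNS, CHARLSON_CONDITIONS, ELIX_COLUMNS, ELIXHAUSER_CONDITIONS

_EXPECTED_COUNTS = {"van_walraven": 31, "charlson": 19}


@dataclass(frozen=True)
class WeightTable:
    """A named map of condition -> integer weight with its provenance."""

    index_name: str
    weights: Mapping[str, int]
    provenance: str

    def __post_init__(self) -> None:
        expected = _EXPECTED_COUNTS.get(self.index_name)
        if expected is not None and len(self.weights) != expected:
            raise DimensionError(
                f"{self.index_name} table must cover exactly {expected} "
                f"conditions, got {len(self.weights)}"
            )

    @property
    def min_score(self) -> int:
        return sum(w for w in self.weights.values() if w < 0)

    @property
    def max_score(self) -> int:
        return sum(w for w in self.weights.values() if w > 0)


def load_weight_table(index_name: str) -> WeightTable:
    """Load a packaged weight table (``van_walraven`` or ``charlson``)."""
    if index_name not in _EXPECTED_COUNTS:
        raise ValueError(f"unknown index {index_name!r}")
    fname = f"{index_name}_weights.csv"
    with resources.files("palcost.data").joinpath(fname).open() as fh:
        table = pd.read_csv(fh)
    order = {"van_walraven": ELIXHAUSER_CONDITIONS, "charlson": CHARLSON_CONDITIONS}[index_name]
    weights = dict(zip(table["condition"], table["weight"].astype(int)))
    if list(weights) != order:
        raise DimensionError(f"packaged {fname} does not match the canonical condition list")
    return WeightTable(index_name, weights, table["source"].iloc[0])


_VW_TABLE: WeightTable | None = None
_CCI_TABLE: WeightTable | None = None


def _default_table(index_name: str) -> WeightTable:
    global _VW_TABLE, _CCI_TABLE
    if index_name == "van_walraven":
        if _VW_TABLE is None:
            _VW_TABLE = load_weight_table("van_walraven")
        return _VW_TABLE
    if _CCI_TABLE is None:
        _CCI_TABLE = load_weight_table("charlson")
    return _CCI_TABLE


def _score(flags, table: WeightTable, columns: list[str]):
    w = np.array(list(table.weights.values()), dtype=int)
    if isinstance(flags, pd.DataFrame):
        missing = [c for c in columns if c not in flags.columns]
        if missing:
            raise DimensionError(f"flag table is missing columns: {missing[:3]}...")
        x = flags[columns].to_numpy(dtype=float)
        return pd.Series(x @ w, index=flags.index).astype(int)
    arr = np.asarray(flags)
    if arr.ndim != 1 or arr.shape[0] != len(w):
        raise DimensionError(
            f"expected {len(w)} flags for the {table.index_name} index, got shape {arr.shape}"
        )
    return int(arr.astype(float) @ w)


def van_walraven_score(elixhauser_flags, table: WeightTable | None = None):
    """Van Walraven score: sum of published weights over 31 Elixhauser flags.

    Accepts a 1-D sequence of 31 booleans (returns ``int``) or a DataFrame
    carrying the ``elix_*`` columns (returns an integer Series).
    """
    table = table or _default_table("van_walraven")
    return _score(elixhauser_flags, table, ELIX_COLUMNS)


def charlson_score(charlson_flags, table: WeightTable | None = None):
    """Charlson Comorbidity Index over 19 condition flags (original weights)."""
    table = table or _default_table("charlson")
    return _score(charlson_flags, table, CCI_COLUMNS)


def score_cohort(records: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of ``records`` with ``vw_score`` and ``charlson_score``."""
    out = records.copy()
    out["vw_score"] = van_walraven_score(records)
    out["charlson_score"] = charlson_score(records)
    return out
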