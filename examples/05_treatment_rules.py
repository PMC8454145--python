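"""Define the two timing-based treatment variables and compare them.

t1: engaged within a fixed number of days (default 3) of admission.
t2: engaged within a fraction (default 1/3) of the *predicted* LOS — a
    day-8 engagement counts as early for a predicted 24-day stay, while a
    day-4 engagement does not count for a predicted 9-day stay.
Late recipients always stay in the comparison group.
"""

import palcost
from palcost import assign_t2, treat

print("day 8 of predicted 24-day stay ->", assign_t2(8, 24.0))
print("day 3 of predicted  9-day stay ->", assign_t2(3, 9.0), "(3/9 = 1/3, boundary inclusive)")
print("day 4 of predicted  9-day stay ->", assign_t2(4, 9.0))

records, _ = palcost.generate_cohort(palcost.GeneratorParams(n_subjects=3000, seed=1))
a1 = treat.assign_t1_cohort(records, d=3)
# use a flat predicted LOS of 9 days for illustration
import pandas as pd
a2 = treat.assign_t2_cohort(records, pd.Series(9.0, index=records.index))
conc = treat.concurrence(a1, a2)
print(f"\nt1 treated: {a1.n_treated}, t2 treated: {a2.n_treated}, "
      f"in both: {conc.n_both} ({conc.percent_overlap}% of t2 group)")
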