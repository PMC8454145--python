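"""Partition admissions into analytic and derivation samples.

The analytic sample holds unique patients at high mortality risk (first
admission, a life-limiting diagnosis, van Walraven score 20+); the derivation
sample relaxes to 13+ and allows repeat admissions of non-analytic patients,
and is used only to fit the predicted-LOS index. Everything else is excluded
with a reason code.
"""

import palcost
from palcost import cohort, scores

records, _ = palcost.generate_cohort(palcost.GeneratorParams(n_subjects=4000, seed=1))
scored = scores.score_cohort(records)
part = cohort.partition(scored, vw_analytic_floor=20, vw_derivation_floor=13)

for name, count in part.counts().items():
    print(f"{name:35s} {count:5d}")
print(f"{'total':35s} {len(records):5d}")
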