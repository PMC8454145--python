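"""Score admissions with the van Walraven/Elixhauser and Charlson indices.

Both indices sum published integer weights over condition flags; the weights
ship as packaged CSV files. The van Walraven score drives cohort eligibility
(analytic floor 20, derivation floor 13); the Charlson index is a prognostic
covariate in the cost models.
"""

import palcost
from palcost import load_weight_table, scores

vw = load_weight_table("van_walraven")
print(f"van Walraven table: {len(vw.weights)} conditions, "
      f"attainable range [{vw.min_score}, {vw.max_score}]")
print(f"  e.g. liver disease {vw.weights['liver_disease']:+d}, "
      f"metastatic cancer {vw.weights['metastatic_cancer']:+d}, "
      f"drug abuse {vw.weights['drug_abuse']:+d}")

records, _ = palcost.generate_cohort(palcost.GeneratorParams(n_subjects=2000, seed=1))
scored = scores.score_cohort(records)
print(f"\ncohort van Walraven: mean {scored['vw_score'].mean():.1f}, "
      f"share at 20+ (analytic floor): {(scored['vw_score'] >= 20).mean():.1%}")
print(f"cohort Charlson: mean {scored['charlson_score'].mean():.1f}")
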