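"""Fit the predicted-LOS (VMLOS) index and categorise admissions.

The index is a multivariable ln(LOS) regression on baseline factors, fit on
the derivation sample, discretised at prediction tertiles into short /
medium / long stay categories; each category carries the mean observed LOS
of its derivation subjects as the predicted LOS in days.
"""

import palcost
from palcost import cohort, fit_vmlos, predict_vmlos, prepare_model_frame, scores

records, _ = palcost.generate_cohort(palcost.GeneratorParams(n_subjects=6000, seed=1))
scored = prepare_model_frame(scores.score_cohort(records))
part = cohort.partition(scored)
derivation = scored.loc[sorted(part.derivation_ids)]
analytic = scored.loc[sorted(part.analytic_ids)]

model = fit_vmlos(derivation)
print(f"derivation n = {len(derivation)}, retained predictors: "
      f"{len(model.retained_predictors)}")
print("category predicted LOS (days):",
      {k: round(v, 1) for k, v in model.category_los.items()})

pred = predict_vmlos(model, analytic)
print("\nanalytic-sample category shares (need not be equal thirds):")
print(pred["vmlos_category"].value_counts(normalize=True).round(2).to_string())
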