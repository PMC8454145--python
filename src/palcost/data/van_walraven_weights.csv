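condition,weight,source
congestive_heart_failure,7,van Walraven et al. Med Care 2009;47(6):626-633
cardiac_arrhythmias,5,van Walraven et al. Med Care 2009;47(6):626-633
valvular_disease,-1,van Walraven et al. Med Care 2009;47(6):626-633
pulmonary_circulation_disorders,4,van Walraven et al. Med Care 2009;47(6):626-633
peripheral_vascular_disorders,2,van Walraven et al. Med Care 2009;47(6):626-633
hypertension_uncomplicated,0,van Walraven et al. Med Care 2009;47(6):626-633
hypertension_complicated,0,van Walraven et al. Med Care 2009;47(6):626-633
paralysis,7,van Walraven et al. Med Care 2009;47(6):626-633
other_neurological_disorders,6,van Walraven et al. Med Care 2009;47(6):626-633
chronic_pulmonary_disease,3,van Walraven et al. Med Care 2009;47(6):626-633
diabetes_uncomplicated,0,van Walraven et al. Med Care 2009;47(6):626-633
diabetes_complicated,0,van Walraven et al. Med Care 2009;47(6):626-633
hypothyroidism,0,van Walraven et al. Med Care 2009;47(6):626-633
renal_failure,5,van Walraven et al. Med Care 2009;47(6):626-633
liver_disease,11,van Walraven et al. Med Care 2009;47(6):626-633
peptic_ulcer_disease,0,van Walraven et al. Med Care 2009;47(6):626-633
aids_hiv,0,van Walraven et al. Med Care 2009;47(6):626-633
lymphoma,9,van Walraven et al. Med Care 2009;47(6):626-633
metastatic_cancer,12,van Walraven et al. Med Care 2009;47(6):626-633
solid_tumor_without_metastasis,4,van Walraven et al. Med Care 2009;47(6):626-633
rheumatoid_arthritis,0,van Walraven et al. Med Care 2009;47(6):626-633
coagulopathy,3,van Walraven et al. Med Care 2009;47(6):626-633
obesity,-4,van Walraven et al. Med Care 2009;47(6):626-633
weight_loss,6,van Walraven et al. Med Care 2009;47(6):626-633
fluid_electrolyte_disorders,5,van Walraven et al. Med Care 2009;47(6):626-633
blood_loss_anemia,-2,van Walraven et al. Med Care 2009;47(6):626-633
deficiency_anemia,-2,van Walraven et al. Med Care 2009;47(6):626-633
alcohol_abuse,0,van Walraven et al. Med Care 2009;47(6):626-633
drug_abuse,-7,van Walraven et al. Med Care 2009;47(6):626-633
psychoses,0,van Walraven et al. Med Care 2009;47(6):626-633
depression,-3,van Walraven et al. Med Care 2009;47(6):626-633
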