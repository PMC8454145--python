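condition,weight,source
myocardial_infarction,1,Charlson et al. J Chronic Dis 1987;40(5):373-383
congestive_heart_failure,1,Charlson et al. J Chronic Dis 1987;40(5):373-383
peripheral_vascular_disease,1,Charlson et al. J Chronic Dis 1987;40(5):373-383
cerebrovascular_disease,1,Charlson et al. J Chronic Dis 1987;40(5):373-383
dementia,1,Charlson et al. J Chronic Dis 1987;40(5):373-383
chronic_pulmonary_disease,1,Charlson et al. J Chronic Dis 1987;40(5):373-383
rheumatologic_disease,1,Charlson et al. J Chronic Dis 1987;40(5):373-383
peptic_ulcer_disease,1,Charlson et al. J Chronic Dis 1987;40(5):373-383
mild_liver_disease,1,Charlson et al. J Chronic Dis 1987;40(5):373-383
diabetes_without_complications,1,Charlson et al. J Chronic Dis 1987;40(5):373-383
diabetes_with_complications,2,Charlson et al. J Chronic Dis 1987;40(5):373-383
hemiplegia_or_paraplegia,2,Charlson et al. J Chronic Dis 1987;40(5):373-383
renal_disease,2,Charlson et al. J Chronic Dis 1987;40(5):373-383
any_malignancy,2,Charlson et al. J Chronic Dis 1987;40(5):373-383
leukemia,2,Charlson et al. J Chronic Dis 1987;40(5):373-383
lymphoma,2,Charlson et al. J Chronic Dis 1987;40(5):373-383
moderate_severe_liver_disease,3,Charlson et al. J Chronic Dis 1987;40(5):373-383
metastatic_solid_tumor,6,Charlson et al. J Chronic Dis 1987;40(5):373-383
aids_hiv,6,Charlson et al. J Chronic Dis 1987;40(5):373-383
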