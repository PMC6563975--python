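# Irwin-style logistic model: CRP, respiratory rate, normal air entry,
# resistin, procalcitonin. COEFFICIENTS ARE SYNTHETIC PLACEHOLDERS
# (provenance: synthetic). Resistin and procalcitonin are never measured in
# ED respiratory cohorts like these, so the derivation-population means
# below are used as constant fill-ins (mean imputation); "normal air entry"
# is the complement of decreased breath sounds.
name: irwin
label: "Irwin (2017), logistic"
form: logistic
source: "synthetic placeholder coefficients; predictor list as published"
derivation_prevalence: 0.12
intercept: -2.0
derivation_constants:
  resistin_ng_ml: 10.0
  procalcitonin_ug_l: 0.5
predictors:
  - variable: crp_mg_l
    transform: log1p
    center: 2.83
    coefficient: 1.0
  - variable: resp_rate
    center: 40
    coefficient: 0.03
  - variable: decreased_breath_sounds
    transform: "not"
    coefficient: -0.5
  - variable: resistin_ng_ml
    center: 10.0
    coefficient: 0.02
  - variable: procalcitonin_ug_l
    center: 0.5
    coefficient: 0.3
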