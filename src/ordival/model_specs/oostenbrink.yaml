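# Oostenbrink-style logistic model: ill appearance, tachypnea, oxygen
# saturation <94%, CRP. COEFFICIENTS ARE SYNTHETIC PLACEHOLDERS
# (provenance: synthetic); the CRP term is log1p-transformed and centred at
# the derivation-population median scale. CRP is truncated at 225 mg/L
# before transformation.
name: oostenbrink
label: "Oostenbrink (2013), logistic"
form: logistic
source: "synthetic placeholder coefficients; predictor list as published"
derivation_prevalence: 0.155
intercept: -2.2
predictors:
  - variable: ill_appearance
    coefficient: 1.0
  - variable: tachypnea
    coefficient: 0.7
  - variable: spo2_pct
    transform: threshold
    op: lt
    cutoff: 94
    coefficient: 0.9
  - variable: crp_mg_l
    transform: log1p
    center: 2.83
    coefficient: 0.9
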