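# Nijman-style logistic model with 11 predictors: age, sex, duration of
# fever, temperature, respiratory rate, heart rate, oxygen saturation,
# capillary refill, retractions, ill appearance and CRP. COEFFICIENTS ARE
# SYNTHETIC PLACEHOLDERS (provenance: synthetic); continuous terms are
# centred at typical ED values so the intercept is interpretable as the
# baseline-risk logit. CRP is truncated at 225 mg/L before transformation.
name: nijman
label: "Nijman (2013), logistic"
form: logistic
source: "synthetic placeholder coefficients; predictor list as published"
derivation_prevalence: 0.063
intercept: -2.2
# Fallbacks for databases where a predictor is wholly unrecorded: the
# derivation-population mean (continuous) or prevalence (binary) is used as
# a constant, i.e. mean imputation.
derivation_constants:
  fever_duration_days: 3.0
  retractions: 0.3
predictors:
  - variable: age_months
    center: 18
    coefficient: -0.005
  - variable: sex
    coefficient: 0.1
  - variable: fever_duration_days
    center: 3
    coefficient: 0.08
  - variable: temperature_c
    center: 38.2
    coefficient: 0.3
  - variable: resp_rate
    center: 40
    coefficient: 0.03
  - variable: heart_rate
    center: 140
    coefficient: 0.005
  - variable: spo2_pct
    center: 98
    coefficient: -0.12
  - variable: cap_refill_prolonged
    coefficient: 0.4
  - variable: retractions
    coefficient: 0.3
  - variable: ill_appearance
    coefficient: 0.6
  - variable: crp_mg_l
    transform: log1p
    center: 2.83
    coefficient: 0.9
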