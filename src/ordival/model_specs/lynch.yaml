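# Lynch-style logistic model: fever, decreased breath sounds, crackles,
# tachypnea. COEFFICIENTS ARE SYNTHETIC PLACEHOLDERS (provenance:
# synthetic): the original publication's coefficients are not shipped; signs
# and magnitudes are clinically plausible, and the large intercept mirrors
# the near-uniform ~90% predicted risks this model produces in all-febrile
# ED populations.
name: lynch
label: "Lynch (2004), logistic"
form: logistic
source: "synthetic placeholder coefficients; predictor list as published"
derivation_prevalence: 0.358
intercept: 1.3
predictors:
  - variable: temperature_c
    transform: threshold
    op: ge
    cutoff: 38.0
    coefficient: 0.6
  - variable: decreased_breath_sounds
    coefficient: 0.7
  - variable: crackles
    coefficient: 0.8
  - variable: tachypnea
    coefficient: 0.6
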