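# Methods

`ordival` validates clinical prediction models for childhood pneumonia
against an ordinal, clinically based reference standard and translates
model output into antibiotic-prescribing decisions. This note documents
the statistical model, the design choices that were genuinely open, and
what the synthetic test bed does and does not show.

## The ordinal reference standard

Chest x-ray is no longer a credible gold standard for bacterial pneumonia,
so each ED visit is placed on a five-point bacterial-to-viral axis:

1. definite/probable bacterial
2. bacterial syndrome
3. unknown bacterial/viral
4. viral syndrome
5. definite/probable viral

Classification uses three inputs with a strict precedence:

1. **Pathogen identification.** A detected bacterium — alone or as a
   bacterial/viral co-infection — gives category 1 (the treatment
   consequences dominate); a virus alone gives category 5.
2. **Working diagnosis.** Without pathogen identification, the clinician's
   end-of-visit diagnosis maps to an initial class via a pre-specified,
   total diagnosis map (bronchiolitis → viral syndrome; pneumonia →
   unknown; …). Unmapped codes raise rather than defaulting, forcing an
   explicit decision per code. Bacterial/viral-syndrome initial classes map
   directly to categories 2/4, *regardless of CRP*.
3. **CRP**, only for the unknown initial class: > 60 mg/L → bacterial
   syndrome (2), ≤ 60 mg/L → viral syndrome (4), not performed → unknown
   (3). The refinement uses the raw measured CRP; the 225 mg/L truncation
   is a modelling-input step only.

The implementation is a total function over the input lattice (verified by
an exhaustive truth-table test). "Bacterial infection" at the binary level
means categories 1–2.

## The model zoo

Seven models are shipped as declarative YAML specs: three rule models
emitting a high/low class (an any-of sign rule; the dyspnoea/"something is
wrong" rule; the first oxygen-saturation split of a decision tree, ≤ 92% —
the source material prints both ≤ 92 and < 92, the table form is shipped
and the comparator is configurable) and four logistic models emitting a
predicted probability (inverse-logit of a linear predictor).

**Coefficient provenance.** The original regression coefficients of the
four logistic models are not public in a usable form here; the shipped
specs carry clearly labelled *synthetic placeholder coefficients* whose
signs and rough magnitudes are clinically plausible (positive CRP,
respiratory-rate and ill-appearance effects; a large positive intercept
for the model known to predict ~90% risk in all-febrile populations). The
deliverable is the validation machinery — spec format, evaluation,
availability gating, ORC, threshold analysis — not any specific
coefficient vector; swapping in published coefficients is a YAML edit.

Supporting machinery:

* **CRP truncation** at 225 mg/L before any logistic transform.
* **Age-banded tachypnea/tachycardia** computed from raw rates with
  WHO/APLS-style cutoffs (respiratory rate: > 60 under 2 months, > 50 at
  2–12 months, > 40 at 1–5 years; heart rate: > 160 under 1 year, > 150 at
  1–2 years, > 140 at 2–5 years); a recorded binary always overrides the
  computed value.
* **Availability gate.** A model is validated only when strictly more than
  50% of its predictors are available (present for ≥ 1 record, directly or
  via proxy). Derivation-constant fill-ins do not count as available.
* **Wholly missing predictors.** Binary predictors get proxy variables
  (retractions for dyspnoea; ill appearance for the "something is wrong"
  gestalt); continuous ones a derivation-population constant (mean
  imputation). A rule predicate on a variable no record carries can never
  fire; such predicates are dropped (logged) once the model has passed the
  availability gate.

## Missing data

Partially missing predictors are imputed *m* = 10 times by default with
chained equations (scikit-learn's iterative imputer, Bayesian-ridge
posterior sampling, booleans round-tripped through {0, 1}); a marginal
hot-deck (draws from the observed marginal) is available as a simpler,
distribution-free alternative. One master seed spawns per-imputation
substreams, so runs are bitwise reproducible and extending *m* preserves
earlier imputations. Observed cells are never altered (tested).

All downstream statistics are computed once per completed dataset and then
**averaged**; the across-imputation SD is reported alongside. Rubin's
variance rules are deliberately not applied to the ORC — the reported
uncertainty is between-imputation spread only, not a confidence interval.

## The ordinal c-statistic

The ORC generalises the AUC to an ordinal outcome: the probability that
two cases from different, randomly selected outcome categories are ranked
correctly. Pairwise AUCs are computed by midranks (exact under ties, ties
count ½), oriented so that the more-bacterial category is expected to
score higher. Two estimators are provided because the literature defines
variants and the phrasing "randomly selected outcome categories" does not
fix one:

* `unweighted_pairs` (default): the simple mean of the pairwise AUCs over
  observed category pairs;
* `pooled_pairs`: the concordant fraction over all cross-category record
  pairs (category pairs weighted by size).

Both reduce to the ordinary AUC for two categories; empty category pairs
are dropped from the average. Rule models are primarily summarised by
category-by-class cross-tabulations; their binary score's ORC is still
computed but flagged as coarse. Models with pooled ORC ≥ 0.55 count as
"performing well" and proceed to threshold analysis (the gate applies to
the pooled mean; `force_thresholds` overrides for exploration).

## Threshold harm/benefit analysis

For a probability model and threshold *t* (defaults 0.10 and 0.15),
children with predicted risk strictly below *t* form the low-risk group.
*Benefit* is the drop from observed to expected prescriptions (observed
minus prescriptions withheld in the low-risk group); *harm*
(under-treatment) counts children in ordinal categories 1–2 who actually
received antibiotics but are labelled low-risk. Both are counts of
observable subgroups; no counterfactual outcome model is involved.
Percentages round half away from zero — the convention that reproduces
every checkable printed percentage from its printed counts.

## Synthetic cohorts

No patient-level data ship with the package; the generator produces
cohorts with the statistical structure the pipeline assumes. Two presets
target the published marginals of the two validation populations
(`rotterdam_like`, n = 248: age median 14 months, CRP median 16 mg/L
measured in 38%, antibiotics 21%, category mix 7/2/38/24/29%;
`coventry_like`, n = 301: CRP median 45 mg/L, tachycardia 65%, several
examination findings wholly unrecorded).

Modelling choices (declared, not inferred from any source):

* Latent category first, drawn from the mixture; observables conditioned
  on it.
* CRP is log-normal per category (location solved from the target
  median/IQR); vitals are truncated normals; binary signs are Bernoulli
  with category-specific logit shifts.
* A single latent severity factor per child correlates temperature,
  respiratory rate, heart rate and SpO2 (configurable loadings);
  fine-grained vital-sign correlation structure is otherwise not emulated.
* `effect_size` multiplies every bacterial-vs-viral shift; 0 yields the
  null where predictor distributions are identical across categories.
* **CRP measurement is structurally absent in the latent unknown
  category** and occurs at a compensating rate elsewhere (so the overall
  measured fraction hits its target). This mirrors the clinical logic — a
  measured CRP would have resolved the category retrospectively — and
  makes the observable classification recover the latent category exactly,
  which the mixture-recovery tests rely on. It also means CRP missingness
  is informative by construction.
* All other missingness is MCAR at the preset rates; a per-category (MAR)
  hook exists for imputation stress tests.
* Prescription is Bernoulli in the latent category with a high-CRP bump,
  calibrated so the observed rates land near their targets.

Passing tests on these cohorts show the machinery is correct under the
declared generative model; they do not show that any model discriminates
in real patients, that real missingness is MCAR, or that the synthetic
placeholder coefficients approximate the published ones.

## Numerical and procedural choices

* Strict comparisons where a boundary matters: CRP 60 mg/L is on the ≤
  (viral) side; "below threshold" excludes the threshold; the availability
  gate excludes exactly 50%.
* Rounding: half away from zero at the printed precision.
* Ties in ranking count ½ everywhere.
* Pipeline order is fixed: read → proxy → reference standard →
  availability gate → imputation → per-imputation prediction and ORC →
  pooling → threshold analysis. The reference standard is computed once on
  observed data (a child without a CRP result stays "unknown" in every
  imputation); imputation serves the prediction models only.
* Every random draw descends from one master seed via spawned
  substreams; identical configurations give byte-identical JSON reports.
* Default problem sizes in tests and the acceptance script (synthetic
  cohorts of 400–10 000, 20 cohort seeds, m = 10) were chosen to put Monte
  Carlo error well inside the asserted tolerances.

## Known limitations

* Synthetic coefficients mean absolute predicted risks — and hence the
  exact threshold-table counts — are illustrative; ranking behaviour and
  the machinery around it are what the tests pin down.
* The reference standard inherits the incorporation bias of any
  working-diagnosis-based outcome; the package reproduces, not resolves,
  that limitation.
* No calibration assessment or recalibration (discrimination is unaffected
  by calibration-in-the-large); no decision-curve/net-benefit weighting;
  no MNAR sensitivity analysis.
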