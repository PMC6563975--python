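# ordival

Ordinal external validation of clinical prediction models for childhood
pneumonia, with threshold-based harm/benefit analysis of antibiotic
prescribing.

## The problem

Pneumonia is the most common bacterial infection in children at the
emergency department, and discriminating bacterial disease (needs
antibiotics) from viral, self-limiting disease is its central diagnostic
challenge. Prediction models for childhood pneumonia were built against
chest x-ray, but x-ray is no longer a credible gold standard. `ordival`
is a toolkit for biostatisticians and clinical epidemiologists who want to
re-validate such models against a *clinical* reference standard and ask
the question that actually matters at the bedside: if we withheld
antibiotics below a predicted-risk threshold, how many prescriptions would
we save, and how many truly bacterial children would we under-treat?

## What it implements

* **An ordinal 5-category reference standard** — definite/probable
  bacterial (1), bacterial syndrome (2), unknown (3), viral syndrome (4),
  definite/probable viral (5) — from working diagnosis, pathogen
  identification and CRP (> 60 mg/L rule), with pathogen findings taking
  precedence and co-infections counted as bacterial.
* **A model zoo** of seven published-model structures as declarative YAML:
  three high/low rule models and four logistic models
  (`inverse_logit(β₀ + Σ βᵢ xᵢ)`, CRP truncated at 225 mg/L). Logistic
  coefficients shipped here are clearly labelled synthetic placeholders
  (see `docs/methods.md`); swapping in published coefficients is a YAML
  edit.
* **Missing-data handling** — proxy variables for wholly unrecorded
  predictors, derivation-population constants (mean imputation) for
  unmeasured biomarkers, chained-equations multiple imputation (m = 10)
  for the rest, and simple averaging of downstream statistics across
  imputations (mean ± SD).
* **The ordinal c-statistic (ORC)** — the AUC generalised to an ordinal
  outcome: the probability that two cases from different, randomly
  selected outcome categories are correctly ranked,
  `ORC = mean over category pairs i<j of AUC(i,j)` (a pooled-pairs variant
  is also provided). Models with ORC ≥ 0.55 count as performing well.
* **Threshold harm/benefit analysis** — at thresholds of 10% and 15%
  predicted risk: size of the low-risk group, expected prescriptions if
  antibiotics were withheld there (benefit), and under-treated children
  (bacterial, actually treated, labelled low-risk; harm).
* **A synthetic cohort generator** with `rotterdam_like` / `coventry_like`
  presets matching published population marginals, a latent true category
  per child, and an `effect_size` dial (0 = no predictor–outcome
  association) — so the full pipeline is testable without patient data.

## Worked example

```bash
python examples/03_validate_models.py
```

```
cohort n = 500, category counts [42, 12, 202, 113, 131]
model        form          avail     ORC      SD  meets>=0.55
irwin        logistic       0.60   0.624   0.013  yes
lynch        logistic       1.00   0.604   0.012  yes
mahabee      rule_any_of    1.00   0.512   0.009  no
neuman       rule_tree      1.00   0.504   0.002  no
nijman       logistic       1.00   0.656   0.013  yes
oostenbrink  logistic       1.00   0.635   0.016  yes
vandenbruel  rule_tree      1.00   0.561   0.004  yes
```

A synthetic Rotterdam-like cohort of 500 is generated, classified on the
5-category standard (counts above run bacterial → viral), imputed 10
times, and every model is scored. The ORC column is the pooled ordinal
c-statistic (0.5 = chance ranking) with its across-imputation SD; `avail`
is the fraction of the model's predictors available in this cohort (0.60
for the biomarker model whose resistin/procalcitonin are filled in by
derivation-population constants). Logistic models above 0.55 then get a
threshold table; `examples/04_threshold_analysis.py` reproduces the
canonical worked example — at a 10% threshold, 130/248 children (52%) are
low-risk, prescriptions fall from 51 (21%) to 35 (14%), and 5 children
(2%) would be under-treated.

The same pipeline runs from the shell:

```bash
ordival validate --profile rotterdam_like --n 500 --imputations 10 \
    --seed 42 --thresholds 0.10,0.15 --out run_out
ordival simulate --profile coventry_like --seed 1 --out coventry.csv
```

or on your own patient-level CSV (`--cohort file.csv`, columns per
`src/ordival/schema.py`, empty cell or `NA` = not recorded).

## Layout

* `src/ordival/` — the library (`cohort_io`, `reference_standard`,
  `model_zoo`, `missing_data`, `metrics`, `decision_analysis`,
  `synthetic_cohort`, `pipeline`, `cli`)
* `src/ordival/model_specs/` — the seven model YAMLs
* `examples/` — one short narrative script per capability
* `docs/methods.md` — the statistical methods note
* `tests/` — pytest suite (unit, property and acceptance tests)
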