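"""Data dictionary for emergency-department cohort tables.

One row per ED visit of a young child with fever and respiratory symptoms.
Column names are canonical snake-case tokens; a user-supplied rename map
(see :func:`ordival.cohort_io.read_cohort`) handles source-specific dialects.
Every optional field distinguishes "absent / not recorded" from false / 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ColumnSpec:
    """Type and constraints for one cohort column."""

    name: str
    kind: str  # "id" | "number" | "boolean" | "category" | "string"
    required: bool = False
    unit: str = ""
    lo: float | None = None
    hi: float | None = None
    categories: tuple[str, ...] = ()


#: Canonical data dictionary. Mandatory columns are ``patient_id`` and
#: ``working_diagnosis``; everything else may be wholly or partly absent.
DATA_DICTIONARY: dict[str, ColumnSpec] = {
    c.name: c
    for c in [
        ColumnSpec("patient_id", "id", required=True),
        ColumnSpec("age_months", "number", unit="months", lo=0.0),
        ColumnSpec("sex", "category", categories=("male", "female")),
        ColumnSpec("temperature_c", "number", unit="degC", lo=30.0, hi=45.0),
        ColumnSpec("fever_duration_days", "number", unit="days", lo=0.0),
        ColumnSpec("resp_rate", "number", unit="breaths/min", lo=0.0),
        ColumnSpec("heart_rate", "number", unit="beats/min", lo=0.0),
        ColumnSpec("spo2_pct", "number", unit="%", lo=0.0, hi=100.0),
        ColumnSpec("ill_appearance", "boolean"),
        ColumnSpec("dyspnoea", "boolean"),
        ColumnSpec("retractions", "boolean"),
        ColumnSpec("nasal_flaring", "boolean"),
        ColumnSpec("crackles", "boolean"),
        ColumnSpec("focal_rales", "boolean"),
        ColumnSpec("decreased_breath_sounds", "boolean"),
        ColumnSpec("wheeze", "boolean"),
        ColumnSpec("chest_pain", "boolean"),
        ColumnSpec("cap_refill_prolonged", "boolean"),
        ColumnSpec("something_wrong", "boolean"),
        ColumnSpec("tachypnea", "boolean"),
        ColumnSpec("tachycardia", "boolean"),
        ColumnSpec("crp_mg_l", "number", unit="mg/L", lo=0.0),
        ColumnSpec("resistin_ng_ml", "number", unit="ng/mL", lo=0.0),
        ColumnSpec("procalcitonin_ug_l", "number", unit="ug/L", lo=0.0),
        ColumnSpec("working_diagnosis", "string", required=True),
        ColumnSpec("bacterial_pathogen_detected", "boolean"),
        ColumnSpec("viral_pathogen_detected", "boolean"),
        ColumnSpec("antibiotics_prescribed", "boolean"),
    ]
}

MANDATORY_COLUMNS = tuple(c.name for c in DATA_DICTIONARY.values() if c.required)

NUMBER_COLUMNS = tuple(c.name for c in DATA_DICTIONARY.values() if c.kind == "number")
BOOLEAN_COLUMNS = tuple(c.name for c in DATA_DICTIONARY.values() if c.kind == "boolean")
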