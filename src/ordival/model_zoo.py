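"""Declarative specification and evaluation of pneumonia prediction models.

Two families are supported:

* **rule models** (``rule_any_of`` / ``rule_tree``) emit a binary high/low
  risk class from predicates — e.g. "high risk iff dyspnoea or the
  clinician feels something is wrong";
* **logistic models** emit a predicted probability
  ``inverse_logit(intercept + sum(coef * transform(x)))``.

Model specs live in YAML files (see ``model_specs/``) so coefficients,
cutoffs and provenance are data, not code. CRP always passes through the
225 mg/L truncation before entering a logistic model. Age-dependent
tachypnea / tachycardia are computed from raw rates with configurable
age-banded cutoffs when the binary field is not recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort_io import Cohort
from .schema import DATA_DICTIONARY

#: Modelling truncation cap for CRP, mg/L.
CRP_TRUNCATION_MG_L = 225.0

#: Age-banded tachypnea cutoffs (age upper bound in months -> breaths/min),
#: WHO/APLS-style; a recorded binary always overrides the computed value.
TACHYPNEA_BANDS: tuple[tuple[float, float], ...] = (
    (2, 60.0),
    (12, 50.0),
    (60, 40.0),
    (float("inf"), 30.0),
)

#: Age-banded tachycardia cutoffs (age upper bound in months -> beats/min).
TACHYCARDIA_BANDS: tuple[tuple[float, float], ...] = (
    (12, 160.0),
    (24, 150.0),
    (60, 140.0),
    (float("inf"), 120.0),
)

_OPS = {
    "ge": np.greater_equal,
    "gt": np.greater,
    "le": np.less_equal,
    "lt": np.less,
    "eq": np.equal,
}

_MODEL_SPEC_DIR = Path(__file__).parent / "model_specs"


class ModelSpecError(ValueError):
    """Raised for malformed or inconsistent model-spec files."""


class UnresolvedPredictorError(ValueError):
    """A required predictor is still absent at evaluation time."""


@dataclass(frozen=True)
class Term:
    """One predictor term: a predicate (rule forms) or a coefficient term.

    ``transform`` options for logistic terms: ``identity``, ``log``,
    ``log1p``, ``threshold`` (binary indicator ``op(x, cutoff)``) and
    ``not`` (logical complement of a boolean). ``center`` subtracts a
    derivation-population reference value before multiplying.
    """

    variable: str
    op: str | None = None
    value: float | None = None
    when: tuple | None = None  # (variable, op, value)
    coefficient: float | None = None
    transform: str = "identity"
    cutoff: float | None = None
    center: float = 0.0


@dataclass(frozen=True)
class ModelSpec:
    """Validated declarative description of one prediction model."""

    name: str
    form: str  # rule_any_of | rule_tree | logistic
    predictors: tuple[Term, ...]
    intercept: float = 0.0
    derivation_constants: dict[str, float] = field(default_factory=dict)
    derivation_prevalence: float | None = None
    source: str = ""
    label: str = ""

    @property
    def is_rule(self) -> bool:
        return self.form in ("rule_any_of", "rule_tree")

    @property
    def predictor_variables(self) -> tuple[str, ...]:
        seen: list[str] = []
        for t in self.predictors:
            if t.variable not in seen:
                seen.append(t.variable)
        return tuple(seen)


def truncate_crp(value: float | np.ndarray) -> float | np.ndarray:
    """Cap CRP at 225 mg/L for modelling input."""
    arr = np.asarray(value, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError("negative CRP")
    out = np.minimum(arr, CRP_TRUNCATION_MG_L)
    return float(out) if np.isscalar(value) or out.ndim == 0 else out


def _known_variable(name: str) -> bool:
    return name in DATA_DICTIONARY


def _parse_term(raw: dict, form: str) -> Term:
    variable = raw.get("variable")
    if not variable or not _known_variable(variable):
        raise ModelSpecError(f"unknown or missing predictor variable: {variable!r}")
    when = None
    if "when" in raw:
        w = raw["when"]
        if not _known_variable(w.get("variable", "")):
            raise ModelSpecError(f"unknown 'when' variable in term {variable!r}")
        when = (w["variable"], w.get("op", "is_true"), w.get("value"))
    if form == "logistic":
        if raw.get("coefficient") is None:
            raise ModelSpecError(f"logistic term {variable!r} lacks a coefficient")
        return Term(
            variable=variable,
            coefficient=float(raw["coefficient"]),
            transform=raw.get("transform", "identity"),
            cutoff=raw.get("cutoff"),
            op=raw.get("op"),
            center=float(raw.get("center", 0.0)),
        )
    op = raw.get("op")
    if op is None:
        raise ModelSpecError(f"rule term {variable!r} lacks a predicate op")
    if op != "is_true" and op not in _OPS:
        raise ModelSpecError(f"unknown predicate op {op!r} in term {variable!r}")
    if op != "is_true" and raw.get("value") is None:
        raise ModelSpecError(f"rule term {variable!r} lacks a comparison value")
    return Term(variable=variable, op=op, value=raw.get("value"), when=when)


def load_model_spec(path: str | Path) -> ModelSpec:
    """Load and validate a YAML model spec."""
    raw = yaml.safe_load(Path(path).read_text())
    form = raw.get("form")
    if form not in ("rule_any_of", "rule_tree", "logistic"):
        raise ModelSpecError(f"unknown model form: {form!r}")
    terms = tuple(_parse_term(t, form) for t in raw.get("predictors", []))
    if not terms:
        raise ModelSpecError("model spec has no predictors")
    return ModelSpec(
        name=raw["name"],
        form=form,
        predictors=terms,
        intercept=float(raw.get("intercept", 0.0)),
        derivation_constants={
            k: float(v) for k, v in (raw.get("derivation_constants") or {}).items()
        },
        derivation_prevalence=raw.get("derivation_prevalence"),
        source=raw.get("source", ""),
        label=raw.get("label", raw["name"]),
    )


def builtin_model_names() -> list[str]:
    return sorted(p.stem for p in _MODEL_SPEC_DIR.glob("*.yaml"))


def load_builtin_model(name: str) -> ModelSpec:
    path = _MODEL_SPEC_DIR / f"{name}.yaml"
    if not path.exists():
        raise ModelSpecError(
            f"no builtin model {name!r}; available: {builtin_model_names()}"
        )
    return load_model_spec(path)


def _banded_cutoff(age_months: pd.Series, bands) -> pd.Series:
    cut = pd.Series(np.nan, index=age_months.index)
    prev = -np.inf
    for hi, threshold in bands:
        mask = (age_months.astype(float) > prev) & (age_months.astype(float) <= hi)
        cut[mask.fillna(False)] = threshold
        prev = hi
    return cut


def derive_tachypnea(frame: pd.DataFrame) -> pd.Series:
    """Age-banded tachypnea from resp_rate; recorded binary wins."""
    computed = pd.Series(pd.NA, index=frame.index, dtype="boolean")
    ok = frame["resp_rate"].notna() & frame["age_months"].notna()
    cut = _banded_cutoff(frame["age_months"], TACHYPNEA_BANDS)
    computed[ok] = (
        frame.loc[ok, "resp_rate"].astype(float) > cut[ok]
    ).astype("boolean")
    if "tachypnea" in frame:
        return frame["tachypnea"].astype("boolean").combine_first(computed)
    return computed


def derive_tachycardia(frame: pd.DataFrame) -> pd.Series:
    computed = pd.Series(pd.NA, index=frame.index, dtype="boolean")
    ok = frame["heart_rate"].notna() & frame["age_months"].notna()
    cut = _banded_cutoff(frame["age_months"], TACHYCARDIA_BANDS)
    computed[ok] = (
        frame.loc[ok, "heart_rate"].astype(float) > cut[ok]
    ).astype("boolean")
    if "tachycardia" in frame:
        return frame["tachycardia"].astype("boolean").combine_first(computed)
    return computed


_DERIVED = {"tachypnea": derive_tachypnea, "tachycardia": derive_tachycardia}
_DERIVED_SOURCES = {"tachypnea": "resp_rate", "tachycardia": "heart_rate"}


def _resolve(
    frame: pd.DataFrame, variable: str, spec: ModelSpec, model_name: str
) -> np.ndarray:
    """Resolve one predictor column to a float array, NaN = absent."""
    if variable in _DERIVED:
        series = _DERIVED[variable](frame)
    elif variable == "sex":
        series = frame["sex"].map({"male": 1.0, "female": 0.0})
    else:
        series = frame[variable]
    values = series.astype("Float64").astype(float).to_numpy()
    if variable in spec.derivation_constants:
        values = np.where(np.isnan(values), spec.derivation_constants[variable], values)
    if variable == "crp_mg_l" and not spec.is_rule:
        present = ~np.isnan(values)
        values = values.copy()
        values[present] = truncate_crp(values[present])
    if np.isnan(values).any():
        raise UnresolvedPredictorError(
            f"model {model_name!r}: predictor {variable!r} unresolved for "
            f"{int(np.isnan(values).sum())} record(s) after proxy/imputation"
        )
    return values


def _predicate(frame: pd.DataFrame, term: Term, spec: ModelSpec) -> np.ndarray:
    x = _resolve(frame, term.variable, spec, spec.name)
    if term.op == "is_true":
        hit = x > 0.5
    else:
        hit = _OPS[term.op](x, float(term.value))
    if term.when is not None:
        wvar, wop, wval = term.when
        wx = _resolve(frame, wvar, spec, spec.name)
        gate = wx > 0.5 if wop == "is_true" else _OPS[wop](wx, float(wval))
        hit = hit & gate
    return hit


def evaluate_rule_model_frame(spec: ModelSpec, frame: pd.DataFrame) -> pd.Series:
    """High/low class over a completed cohort table: high iff any predicate holds."""
    if not spec.is_rule:
        raise ModelSpecError(f"{spec.name} is not a rule model")
    high = np.zeros(len(frame), dtype=bool)
    for term in spec.predictors:
        high |= _predicate(frame, term, spec)
    return pd.Series(np.where(high, "high", "low"), index=frame.index, name=spec.name)


def evaluate_logistic_model_frame(spec: ModelSpec, frame: pd.DataFrame) -> pd.Series:
    """Predicted probabilities over a completed cohort table."""
    if spec.is_rule:
        raise ModelSpecError(f"{spec.name} is not a logistic model")
    lp = np.full(len(frame), spec.intercept, dtype=float)
    for term in spec.predictors:
        x = _resolve(frame, term.variable, spec, spec.name)
        if term.transform == "identity":
            z = x
        elif term.transform == "log":
            z = np.log(x)
        elif term.transform == "log1p":
            z = np.log1p(x)
        elif term.transform == "not":
            z = 1.0 - (x > 0.5)
        elif term.transform == "threshold":
            z = _OPS[term.op or "ge"](x, float(term.cutoff)).astype(float)
        else:
            raise ModelSpecError(f"unknown transform {term.transform!r}")
        lp += term.coefficient * (z - term.center)
    if not np.all(np.isfinite(lp)):
        raise ValueError(f"model {spec.name!r}: non-finite linear predictor")
    risk = 1.0 / (1.0 + np.exp(-lp))
    return pd.Series(risk, index=frame.index, name=spec.name)


def _one_row(record: pd.Series | dict) -> pd.DataFrame:
    if isinstance(record, pd.Series):
        frame = record.to_frame().T
    else:
        frame = pd.DataFrame([record])
    for col, cspec in DATA_DICTIONARY.items():
        if col not in frame.columns:
            frame[col] = pd.NA
        if cspec.kind == "number":
            frame[col] = frame[col].astype("Float64")
        elif cspec.kind == "boolean":
            frame[col] = frame[col].astype("boolean")
    return frame


def evaluate_rule_model(spec: ModelSpec, record: pd.Series | dict) -> str:
    """Classify a single record as ``"high"`` or ``"low"`` risk."""
    return str(evaluate_rule_model_frame(spec, _one_row(record)).iloc[0])


def evaluate_logistic_model(spec: ModelSpec, record: pd.Series | dict) -> float:
    """Predicted probability of bacterial pneumonia for a single record."""
    return float(evaluate_logistic_model_frame(spec, _one_row(record)).iloc[0])


def predictor_availability(spec: ModelSpec, cohort: Cohort) -> tuple[float, bool]:
    """Fraction of the model's predictors available in a cohort.

    A predictor is available if it is present for at least one record,
    directly or via a proxy substitution (derived binaries count if their
    source rate is recorded). Derivation-constant fill-ins do NOT count as
    available. The inclusion gate is strict: fraction must exceed 0.5.
    """
    variables = spec.predictor_variables
    n_avail = 0
    for var in variables:
        if var in _DERIVED:
            present = cohort.data[var].notna().any() or (
                cohort.data[_DERIVED_SOURCES[var]].notna().any()
                and cohort.data["age_months"].notna().any()
            )
        else:
            present = cohort.data[var].notna().any()
        n_avail += bool(present)
    fraction = n_avail / len(variables)
    return fraction, fraction > 0.5
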