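"""Multiple imputation and cross-imputation pooling.

Partially missing predictors are imputed *m* times (default: chained
equations, mirroring the mice approach; a dependency-light marginal
hot-deck is also provided). Wholly missing continuous predictors cannot be
imputed from the data and instead receive a constant from the model's
derivation population (:func:`constant_impute`).

Downstream statistics are computed once per completed dataset and then
averaged (:func:`pool_results`); only the mean and the across-imputation
standard deviation are reported — Rubin's variance rules are deliberately
not applied to the ordinal c-statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

from .cohort_io import Cohort
from .schema import BOOLEAN_COLUMNS, DATA_DICTIONARY, NUMBER_COLUMNS

METHODS = ("chained_equations", "marginal_hotdeck")


@dataclass
class ImputationSet:
    """m completed cohorts sharing all observed values."""

    completed_cohorts: list[Cohort]
    m: int
    seed: int
    method: str


@dataclass(frozen=True)
class PooledEstimate:
    """Across-imputation mean and standard deviation of one statistic."""

    mean: float
    sd: float
    per_imputation_values: tuple[float, ...]


def pool_results(per_imputation_values) -> PooledEstimate:
    """Average a statistic computed on each completed dataset.

    The SD is the sample standard deviation across imputations (0 for a
    single imputation).
    """
    values = [float(v) for v in per_imputation_values]
    if not values:
        raise ValueError("cannot pool an empty list of results")
    if not all(math.isfinite(v) for v in values):
        raise ValueError("non-finite value among per-imputation results")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return PooledEstimate(mean=mean, sd=sd, per_imputation_values=tuple(values))


def constant_impute(cohort: Cohort, variable: str, derivation_value: float) -> Cohort:
    """Fill every absent value of ``variable`` with a derivation constant."""
    if not math.isfinite(float(derivation_value)):
        raise ValueError(f"derivation value for {variable!r} is not finite")
    out = cohort.copy()
    absent = out.data[variable].isna()
    if absent.any():
        out.data.loc[absent, variable] = derivation_value
        out.provenance.loc[absent, variable] = "imputed:constant"
    return out


def _numeric_matrix(data: pd.DataFrame, columns: list[str]) -> np.ndarray:
    mat = np.empty((len(data), len(columns)), dtype=float)
    for j, col in enumerate(columns):
        if col == "sex":
            mat[:, j] = data["sex"].map({"male": 1.0, "female": 0.0}).astype(
                "Float64"
            ).astype(float)
        else:
            mat[:, j] = data[col].astype("Float64").astype(float)
    return mat


def _writeback(data: pd.DataFrame, col: str, filled: np.ndarray) -> None:
    spec = DATA_DICTIONARY[col]
    if spec.kind == "boolean":
        data[col] = pd.array(filled > 0.5, dtype="boolean")
    else:
        values = filled.astype(float)
        if spec.lo is not None:
            values = np.maximum(values, spec.lo)
        if spec.hi is not None:
            values = np.minimum(values, spec.hi)
        data[col] = pd.array(values, dtype="Float64")


def impute_multiple(
    cohort: Cohort,
    variables: list[str],
    m: int = 10,
    seed: int = 0,
    method: str = "chained_equations",
    auxiliary: list[str] | None = None,
    max_iter: int = 10,
) -> ImputationSet:
    """Impute the listed variables *m* times.

    Parameters
    ----------
    variables
        Columns whose absent cells must be filled in every completed
        cohort. Each needs at least one observed value.
    auxiliary
        Extra columns fed to the chained-equations imputation model (by
        default every numeric/boolean dictionary column with at least one
        observed value — clinical signs, diagnostics and treatment).
    seed
        Master seed; per-imputation substreams are spawned from it, so the
        same call is bitwise reproducible and extending *m* keeps the
        earlier imputations unchanged.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    for var in variables:
        if var not in cohort.data.columns:
            raise KeyError(f"unknown variable {var!r}")
        if cohort.data[var].notna().sum() == 0:
            raise ValueError(
                f"variable {var!r} has no observed values; use a proxy or "
                f"constant_impute with a derivation-population value"
            )

    child_seeds = [
        int(s.generate_state(1)[0] % (2**31 - 1))
        for s in np.random.SeedSequence(seed).spawn(m)
    ]
    targets = [v for v in variables if cohort.data[v].isna().any()]

    if auxiliary is None:
        auxiliary = [
            c
            for c in (*NUMBER_COLUMNS, *BOOLEAN_COLUMNS, "sex")
            if c in cohort.data.columns and cohort.data[c].notna().any()
        ]
    model_cols = list(dict.fromkeys([*targets, *auxiliary]))

    completed: list[Cohort] = []
    for k in range(m):
        out = cohort.copy()
        if targets:
            if method == "chained_equations":
                mat = _numeric_matrix(out.data, model_cols)
                imputer = IterativeImputer(
                    sample_posterior=True,
                    max_iter=max_iter,
                    random_state=child_seeds[k],
                    keep_empty_features=True,
                )
                filled = imputer.fit_transform(mat)
                for j, col in enumerate(model_cols):
                    if col not in targets:
                        continue
                    absent = out.data[col].isna()
                    merged = mat[:, j].copy()
                    merged[absent.to_numpy()] = filled[absent.to_numpy(), j]
                    _writeback(out.data, col, merged)
                    out.provenance.loc[absent, col] = "imputed:chained_equations"
            else:  # marginal_hotdeck
                rng = np.random.default_rng(child_seeds[k])
                for col in targets:
                    absent = out.data[col].isna()
                    observed = out.data.loc[~absent, col].to_numpy()
                    draws = rng.choice(observed, size=int(absent.sum()), replace=True)
                    out.data.loc[absent, col] = pd.array(
                        draws, dtype=out.data[col].dtype
                    )
                    out.provenance.loc[absent, col] = "imputed:marginal_hotdeck"
        completed.append(out)
    return ImputationSet(completed_cohorts=completed, m=m, seed=seed, method=method)
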