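"""Reading, validating and normalising patient-level cohort tables.

A :class:`Cohort` wraps a typed :class:`pandas.DataFrame` (one row per ED
visit) together with per-cell provenance ("raw", "proxy:<source>",
"imputed:<how>") so that every substituted value stays auditable.

Missingness is first-class: an empty cell or a literal ``NA`` reads as
absent, never as ``False`` or ``0``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import (
    BOOLEAN_COLUMNS,
    DATA_DICTIONARY,
    MANDATORY_COLUMNS,
    NUMBER_COLUMNS,
)

_NA_TOKENS = {"", "na", "nan", "none", "null"}
_TRUE_TOKENS = {"1", "true", "t", "yes", "y"}
_FALSE_TOKENS = {"0", "false", "f", "no", "n"}


class CohortError(ValueError):
    """Raised for structurally invalid cohort tables or proxy maps."""


@dataclass
class Cohort:
    """An ordered collection of ED-visit records with provenance.

    Parameters
    ----------
    data
        Typed table, one row per visit; columns are a subset of the data
        dictionary plus mandatory ``patient_id`` / ``working_diagnosis``.
    name
        Cohort label (e.g. ``"rotterdam"``).
    provenance
        Same shape as ``data``; each cell is ``"raw"`` where a value was
        observed, ``""`` where absent, or ``"proxy:<var>"`` /
        ``"imputed:<how>"`` after substitution.
    """

    data: pd.DataFrame
    name: str = "cohort"
    provenance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.provenance is None:
            prov = pd.DataFrame("", index=self.data.index, columns=self.data.columns)
            prov = prov.mask(self.data.notna(), "raw")
            self.provenance = prov
        if self.data["patient_id"].duplicated().any():
            dups = self.data.loc[self.data["patient_id"].duplicated(), "patient_id"]
            raise CohortError(f"duplicate patient_id values: {sorted(set(dups))}")

    def __len__(self) -> int:
        return len(self.data)

    def copy(self) -> "Cohort":
        return Cohort(self.data.copy(), self.name, self.provenance.copy())

    def missingness(self) -> pd.Series:
        """Fraction absent per column (0.0 = fully observed)."""
        return self.data.isna().mean()

    def missingness_report(self) -> dict:
        n = len(self.data)
        return {
            "cohort": self.name,
            "n_records": n,
            "columns": {
                col: {
                    "n_present": int(self.data[col].notna().sum()),
                    "n_absent": int(self.data[col].isna().sum()),
                    "fraction_missing": float(self.data[col].isna().mean()) if n else 1.0,
                }
                for col in self.data.columns
            },
        }


def _coerce_number(raw: pd.Series, name: str) -> pd.Series:
    out = pd.to_numeric(raw, errors="coerce").astype("Float64")
    spec = DATA_DICTIONARY[name]
    if spec.lo is not None:
        out = out.mask(out < spec.lo)
    if spec.hi is not None:
        out = out.mask(out > spec.hi)
    return out


def _coerce_boolean(raw: pd.Series) -> pd.Series:
    toks = raw.astype("string").str.strip().str.lower()
    out = pd.Series(pd.NA, index=raw.index, dtype="boolean")
    out[toks.isin(_TRUE_TOKENS)] = True
    out[toks.isin(_FALSE_TOKENS)] = False
    return out


def read_cohort(
    path: str | Path,
    name: str | None = None,
    rename_map: dict[str, str] | None = None,
) -> Cohort:
    """Read a delimited cohort table and type it against the data dictionary.

    Unparseable or out-of-range cells become absent (``NA``); columns not in
    the dictionary are dropped; dictionary columns missing from the file are
    created fully absent so downstream availability logic sees them as
    unmeasured rather than crashing.

    Raises
    ------
    CohortError
        If a mandatory column is missing or ``patient_id`` has duplicates.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if rename_map:
        frame = frame.rename(columns=rename_map)
    frame = frame.replace({tok: None for tok in _NA_TOKENS} | {"NA": None})
    # case-insensitive NA handling for string frames read with keep_default_na=False
    frame = frame.apply(
        lambda s: s.mask(s.astype("string").str.strip().str.lower().isin(_NA_TOKENS))
    )

    for col in MANDATORY_COLUMNS:
        if col not in frame.columns:
            raise CohortError(f"mandatory column missing: {col!r}")
        if frame[col].isna().any():
            raise CohortError(f"mandatory column {col!r} has empty cells")

    data = pd.DataFrame(index=frame.index)
    for col, spec in DATA_DICTIONARY.items():
        if col not in frame.columns:
            if spec.kind == "number":
                data[col] = pd.Series(pd.NA, index=frame.index, dtype="Float64")
            elif spec.kind == "boolean":
                data[col] = pd.Series(pd.NA, index=frame.index, dtype="boolean")
            else:
                data[col] = pd.Series(pd.NA, index=frame.index, dtype="string")
            continue
        raw = frame[col]
        if spec.kind == "number":
            data[col] = _coerce_number(raw, col)
        elif spec.kind == "boolean":
            data[col] = _coerce_boolean(raw)
        elif spec.kind == "category":
            toks = raw.astype("string").str.strip().str.lower()
            data[col] = toks.where(toks.isin(spec.categories)).astype("string")
        else:
            data[col] = raw.astype("string").str.strip()

    return Cohort(data, name=name or path.stem)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort as CSV with empty cells for absent values."""
    out = cohort.data.copy()
    for col in BOOLEAN_COLUMNS:
        if col in out.columns:
            out[col] = out[col].map({True: "true", False: "false"})
    out.to_csv(path, index=False, na_rep="")


def write_missingness_report(cohort: Cohort, path: str | Path) -> None:
    Path(path).write_text(json.dumps(cohort.missingness_report(), indent=2))


def apply_proxy_map(cohort: Cohort, proxy_map: dict[str, str]) -> Cohort:
    """Fill absent target variables from recorded proxy variables.

    For every record where ``target`` is absent and ``source`` present, the
    target takes the source value and provenance becomes
    ``"proxy:<source>"``. Present target values are never overwritten, which
    also makes the operation idempotent.

    Raises
    ------
    CohortError
        If a source variable is not in the schema, or the map contains a
        cycle (``a -> b -> ... -> a``), which would make the result depend
        on application order.
    """
    for target, source in proxy_map.items():
        if target not in DATA_DICTIONARY:
            raise CohortError(f"proxy target not in data dictionary: {target!r}")
        if source not in DATA_DICTIONARY:
            raise CohortError(f"proxy source not in data dictionary: {source!r}")
    for start in proxy_map:
        seen, node = {start}, proxy_map[start]
        while node in proxy_map:
            if node in seen:
                raise CohortError(f"proxy cycle involving {node!r}")
            seen.add(node)
            node = proxy_map[node]

    out = cohort.copy()
    for target, source in proxy_map.items():
        fill = out.data[target].isna() & out.data[source].notna()
        if fill.any():
            out.data.loc[fill, target] = out.data.loc[fill, source].astype(
                out.data[target].dtype
            )
            out.provenance.loc[fill, target] = f"proxy:{source}"
    return out
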