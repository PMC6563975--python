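"""Ordinal clinical reference standard for childhood respiratory infection.

Instead of chest x-ray, each child is placed on a five-point bacterial-to-
viral axis using three inputs, in strict precedence order:

1. pathogen identification (blood culture / viral PCR) — a detected
   bacterium, alone or as a co-infection, classifies the child as
   definite/probable bacterial given the consequences for treatment; a
   virus alone as definite/probable viral;
2. the clinician's working diagnosis at the end of the ED visit, mapped
   to an initial class (bacterial syndrome / viral syndrome / unknown);
3. for the unknown initial class only, the C-reactive protein level:
   > 60 mg/L moves the child to bacterial syndrome, <= 60 mg/L to viral
   syndrome, no CRP performed leaves the child unknown.

Categories: 1 definite/probable bacterial, 2 bacterial syndrome,
3 unknown bacterial/viral, 4 viral syndrome, 5 definite/probable viral.
"""

from __future__ import annotations

import enum
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort_io import Cohort

#: CRP refinement cutoff in mg/L; values strictly above are "high".
CRP_CUTOFF_MG_L = 60.0


class InitialClass(str, enum.Enum):
    """First-step class derived from the working diagnosis alone."""

    BACTERIAL_SYNDROME = "bacterial_syndrome"
    VIRAL_SYNDROME = "viral_syndrome"
    UNKNOWN = "unknown"


class ReferenceCategory(enum.IntEnum):
    """Ordinal outcome; lower = more bacterial."""

    DEFINITE_PROBABLE_BACTERIAL = 1
    BACTERIAL_SYNDROME = 2
    UNKNOWN = 3
    VIRAL_SYNDROME = 4
    DEFINITE_PROBABLE_VIRAL = 5

    @property
    def label(self) -> str:
        return self.name.lower()


class UnmappedDiagnosisError(KeyError):
    """A working-diagnosis code has no entry in the diagnosis map."""


class DiagnosisMap:
    """Mapping from working-diagnosis codes to initial classes.

    The map must be total over the codes observed in a cohort; unmapped
    codes raise rather than being silently dropped, forcing an explicit
    classification decision for every diagnosis.
    """

    def __init__(self, entries: dict[str, InitialClass | str]):
        self.entries = {
            str(code): InitialClass(value) for code, value in entries.items()
        }

    def __contains__(self, code: str) -> bool:
        return code in self.entries

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DiagnosisMap":
        return cls(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump({k: v.value for k, v in self.entries.items()})
        )


def default_diagnosis_map() -> DiagnosisMap:
    """Diagnosis map shipped with the package (ED respiratory codes)."""
    path = Path(__file__).parent / "data" / "diagnosis_map.yaml"
    return DiagnosisMap.from_yaml(path)


def map_working_diagnosis(code: str, dx_map: DiagnosisMap) -> InitialClass:
    """Deterministic lookup of the initial class for one diagnosis code."""
    if code not in dx_map:
        raise UnmappedDiagnosisError(
            f"working diagnosis {code!r} not in diagnosis map; add an explicit entry"
        )
    return dx_map.entries[code]


def refine_category(
    initial: InitialClass,
    bacterial_detected: bool,
    viral_detected: bool,
    crp: float | None,
) -> ReferenceCategory:
    """Second refinement step: pathogen identification, then CRP.

    ``crp`` is the raw measured value in mg/L, or ``None`` if CRP was not
    performed (the modelling truncation at 225 mg/L does not apply here).
    """
    if crp is not None and crp < 0:
        raise ValueError(f"negative CRP: {crp}")
    if bacterial_detected:  # incl. bacterial/viral co-infection
        return ReferenceCategory.DEFINITE_PROBABLE_BACTERIAL
    if viral_detected:
        return ReferenceCategory.DEFINITE_PROBABLE_VIRAL
    if initial is InitialClass.BACTERIAL_SYNDROME:
        return ReferenceCategory.BACTERIAL_SYNDROME
    if initial is InitialClass.VIRAL_SYNDROME:
        return ReferenceCategory.VIRAL_SYNDROME
    # unknown initial class: CRP decides, if performed
    if crp is None:
        return ReferenceCategory.UNKNOWN
    if crp > CRP_CUTOFF_MG_L:
        return ReferenceCategory.BACTERIAL_SYNDROME
    return ReferenceCategory.VIRAL_SYNDROME


def classify_cohort(
    cohort: Cohort, dx_map: DiagnosisMap
) -> tuple[pd.Series, np.ndarray]:
    """Assign every record its ordinal category.

    Returns
    -------
    categories
        Integer series (1..5) aligned with the cohort rows.
    counts
        Length-5 count vector (index 0 = category 1); sums to the cohort size.
    """
    data = cohort.data
    cats = []
    for _, row in data.iterrows():
        initial = map_working_diagnosis(str(row["working_diagnosis"]), dx_map)
        crp = row["crp_mg_l"]
        cats.append(
            int(
                refine_category(
                    initial,
                    bool(row["bacterial_pathogen_detected"])
                    if pd.notna(row["bacterial_pathogen_detected"])
                    else False,
                    bool(row["viral_pathogen_detected"])
                    if pd.notna(row["viral_pathogen_detected"])
                    else False,
                    None if pd.isna(crp) else float(crp),
                )
            )
        )
    categories = pd.Series(cats, index=data.index, name="reference_category")
    counts = np.bincount(categories, minlength=6)[1:6]
    return categories, counts


def bacterial_flag(category: int | ReferenceCategory) -> bool:
    """True iff the category counts as bacterial infection (1 or 2)."""
    category = int(category)
    if not 1 <= category <= 5:
        raise ValueError(f"invalid category: {category}")
    return category <= 2
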