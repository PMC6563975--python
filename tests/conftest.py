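import textwrap

import pandas as pd
import pytest

from ordival.cohort_io import Cohort, read_cohort
from ordival.schema import DATA_DICTIONARY


@pytest.fixture
def write_csv(tmp_path):
    """Write CSV text to a temp file and return its path."""

    def _write(text, name="cohort.csv"):
        path = tmp_path / name
        path.write_text(textwrap.dedent(text).strip() + "\n")
        return path

    return _write


def make_cohort(records, name="test"):
    """Build a typed Cohort directly from a list of record dicts.

    Unspecified dictionary columns become absent; booleans/numbers get
    their nullable dtypes, so the frame matches what read_cohort produces.
    """
    frame = pd.DataFrame(records)
    for col, spec in DATA_DICTIONARY.items():
        dtype = {"number": "Float64", "boolean": "boolean"}.get(spec.kind, "string")
        if col not in frame.columns:
            frame[col] = pd.Series(pd.NA, index=frame.index, dtype=dtype)
        else:
            frame[col] = frame[col].astype(dtype)
    return Cohort(frame[[c for c in DATA_DICTIONARY]], name=name)


@pytest.fixture
def tiny_cohort():
    """Six fully-typed records spanning several diagnosis routes."""
    return make_cohort(
        [
            dict(patient_id="p1", age_months=20, working_diagnosis="pneumonia",
                 bacterial_pathogen_detected=True, viral_pathogen_detected=False,
                 antibiotics_prescribed=True, crp_mg_l=120.0),
            dict(patient_id="p2", age_months=8, working_diagnosis="bacterial_pneumonia",
                 bacterial_pathogen_detected=False, viral_pathogen_detected=False,
                 antibiotics_prescribed=True),
            dict(patient_id="p3", age_months=30, working_diagnosis="pneumonia",
                 bacterial_pathogen_detected=False, viral_pathogen_detected=False,
                 antibiotics_prescribed=False),
            dict(patient_id="p4", age_months=12, working_diagnosis="bronchiolitis",
                 bacterial_pathogen_detected=False, viral_pathogen_detected=False,
                 antibiotics_prescribed=False, crp_mg_l=80.0),
            dict(patient_id="p5", age_months=6, working_diagnosis="bronchiolitis",
                 bacterial_pathogen_detected=False, viral_pathogen_detected=True,
                 antibiotics_prescribed=False),
            dict(patient_id="p6", age_months=18, working_diagnosis="pneumonia",
                 bacterial_pathogen_detected=False, viral_pathogen_detected=False,
                 antibiotics_prescribed=True, crp_mg_l=20.0),
        ]
    )
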