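"""Synthetic ED cohort generator.

Emulates the statistical structure of paediatric ED populations of young
children with fever and cough/dyspnoea: a latent 5-category bacterial-to-
viral outcome, category-dependent predictor distributions, realistic
missingness, and an antibiotic-prescription process driven by category and
CRP. Two presets mirror the published marginals of the Rotterdam (n=248)
and Coventry (n=301) validation populations.

Modelling choices (see docs/methods.md):

* CRP is log-normal per category, vitals are truncated normals; medians
  and IQRs are declared targets, functional forms a modelling choice.
* A single latent severity factor per child correlates the vitals.
* ``effect_size`` scales every bacterial-vs-viral shift; 0 gives the null
  (identical predictor distributions across categories).
* CRP measurement is structurally absent in the latent "unknown" category
  and occurs at a compensating rate elsewhere, so the observable
  reference-standard rules recover the latent category exactly while the
  overall measured fraction matches its target.
* All other missingness is MCAR at the preset rates by default; a
  category-dependent (MAR) hook is available for imputation stress tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort_io import Cohort

_Z75 = 0.6744897501960817  # 75th percentile of the standard normal


@dataclass(frozen=True)
class ContinuousSpec:
    """Target median/IQR plus per-category location shifts.

    ``dist`` is ``lognormal`` or ``normal``; for lognormal the shifts act
    on the log-median. Shifts are multiplied by the profile effect size.
    """

    median: float
    iqr: tuple[float, float]
    dist: str = "normal"
    shifts: tuple[float, float, float, float, float] = (0, 0, 0, 0, 0)
    lo: float | None = None
    hi: float | None = None
    severity_loading: float = 0.0

    def sigma(self) -> float:
        lo, hi = self.iqr
        if self.dist == "lognormal":
            return math.log(hi / lo) / (2 * _Z75)
        return (hi - lo) / (2 * _Z75)


@dataclass(frozen=True)
class BinarySpec:
    """Baseline rate plus per-category logit shifts (scaled by effect size)."""

    rate: float
    shifts: tuple[float, float, float, float, float] = (0, 0, 0, 0, 0)


@dataclass(frozen=True)
class CohortProfile:
    name: str
    n: int
    category_mixture: tuple[float, float, float, float, float]
    continuous: dict[str, ContinuousSpec]
    binaries: dict[str, BinarySpec]
    missingness: dict[str, float]
    crp_measured_fraction: float
    rx_rates: tuple[float, float, float, float, float]
    rx_crp_bonus: float = 0.15
    male_fraction: float = 0.6
    effect_size: float = 1.0
    seed: int = 0
    mar_missingness: dict[str, tuple[float, ...]] = field(default_factory=dict)
    #: descriptive targets not directly parameterised (e.g. derived-sign rates)
    target_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        mix = np.asarray(self.category_mixture, dtype=float)
        if mix.size != 5 or np.any(mix < 0) or not math.isclose(mix.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("category mixture must be 5 non-negative values summing to 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        for name, rate in self.missingness.items():
            if not 0 <= rate <= 1:
                raise ValueError(f"missingness rate for {name!r} outside [0,1]")


#: Working-diagnosis pools per latent category (1-indexed).
_DX_POOLS = {
    1: ("pneumonia", "lrti"),
    2: ("bacterial_pneumonia", "empyema"),
    3: ("pneumonia", "lrti"),
    4: ("bronchiolitis", "viral_wheeze", "uri"),
    5: ("bronchiolitis", "viral_wheeze", "uri"),
}


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    return math.log(p / (1.0 - p))


def generate_cohort(
    profile: CohortProfile, seed: int | None = None
) -> tuple[Cohort, pd.Series]:
    """Draw one synthetic cohort.

    Returns the observable :class:`~ordival.cohort_io.Cohort` (with
    missingness applied) and the per-record latent true category, so tests
    can score both the observable reference-standard path and the latent
    oracle path.
    """
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    n = profile.n
    es = profile.effect_size
    cat = rng.choice(np.arange(1, 6), size=n, p=np.asarray(profile.category_mixture))
    severity = rng.standard_normal(n)

    data: dict[str, object] = {}
    data["patient_id"] = [f"{profile.name}-{i:05d}" for i in range(n)]
    data["sex"] = np.where(
        rng.random(n) < profile.male_fraction, "male", "female"
    ).astype(object)

    values: dict[str, np.ndarray] = {}
    for var, spec in profile.continuous.items():
        shift = np.asarray(spec.shifts, dtype=float)[cat - 1] * es
        rho = spec.severity_loading
        noise = rho * severity + math.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(n)
        if spec.dist == "lognormal":
            x = np.exp(math.log(spec.median) + shift + spec.sigma() * noise)
        else:
            x = spec.median + shift + spec.sigma() * noise
        if spec.lo is not None or spec.hi is not None:
            x = np.clip(x, spec.lo, spec.hi)
        values[var] = x

    for var, spec in profile.binaries.items():
        logit = _logit(min(max(spec.rate, 1e-6), 1 - 1e-6))
        p = _sigmoid(logit + np.asarray(spec.shifts, dtype=float)[cat - 1] * es)
        values[var] = rng.random(n) < p

    # Latent-category-consistent observables for the reference standard.
    dx = np.array(
        [rng.choice(_DX_POOLS[int(c)]) for c in cat], dtype=object
    )
    bact = cat == 1
    viral = (cat == 5) | (bact & (rng.random(n) < 0.2))  # some co-infections
    data["working_diagnosis"] = dx
    data["bacterial_pathogen_detected"] = bact
    data["viral_pathogen_detected"] = viral

    # CRP measurement: never in the latent unknown category, compensated
    # elsewhere so the overall measured fraction hits its target.
    p_unknown = profile.category_mixture[2]
    r = profile.crp_measured_fraction / max(1e-9, 1.0 - p_unknown)
    crp_measured = (cat != 3) & (rng.random(n) < r)

    # Antibiotic prescription: category base rate plus a high-CRP bump.
    rx_p = np.asarray(profile.rx_rates, dtype=float)[cat - 1]
    crp_high = crp_measured & (values["crp_mg_l"] > 60.0)
    rx_p = np.clip(rx_p + profile.rx_crp_bonus * crp_high, 0.0, 0.95)
    data["antibiotics_prescribed"] = rng.random(n) < rx_p

    # Missingness: CRP by the measurement rule, everything else MCAR (or
    # MAR via per-category rates when configured).
    frame = pd.DataFrame(data)
    for var, x in values.items():
        if var == "crp_mg_l":
            col = pd.array(np.where(crp_measured, x, np.nan), dtype="Float64")
        else:
            if var in profile.mar_missingness:
                miss_p = np.asarray(profile.mar_missingness[var], dtype=float)[cat - 1]
            else:
                miss_p = profile.missingness.get(var, 0.0)
            missing = rng.random(n) < miss_p
            if var in profile.continuous:
                col = pd.array(np.where(missing, np.nan, x), dtype="Float64")
            else:
                col = pd.array(x, dtype="boolean")
                col[missing] = pd.NA
        frame[var] = col

    from .schema import DATA_DICTIONARY  # local to avoid cycle at import time

    for name, cspec in DATA_DICTIONARY.items():
        if name in frame.columns:
            continue
        dtype = {"number": "Float64", "boolean": "boolean"}.get(cspec.kind, "string")
        frame[name] = pd.Series(pd.NA, index=frame.index, dtype=dtype)
    frame = frame[[c for c in DATA_DICTIONARY]]
    for name, cspec in DATA_DICTIONARY.items():
        if cspec.kind == "number":
            frame[name] = frame[name].astype("Float64")
        elif cspec.kind == "boolean":
            frame[name] = frame[name].astype("boolean")
        else:
            frame[name] = frame[name].astype("string")

    cohort = Cohort(frame, name=profile.name)
    truth = pd.Series(cat, index=frame.index, name="true_category")
    return cohort, truth


def _rotterdam_profile(n: int = 248, effect_size: float = 1.0, seed: int = 0) -> CohortProfile:
    return CohortProfile(
        name="rotterdam_like",
        n=n,
        category_mixture=(18 / 248, 4 / 248, 94 / 248, 59 / 248, 73 / 248),
        continuous={
            "age_months": ContinuousSpec(14, (7, 27), "lognormal", lo=1, hi=60),
            "temperature_c": ContinuousSpec(
                38.2, (37.4, 39.1), shifts=(0.5, 0.5, 0, -0.1, -0.15),
                lo=35, hi=42, severity_loading=0.4
            ),
            "fever_duration_days": ContinuousSpec(
                3, (2, 4), "lognormal", shifts=(0.2, 0.2, 0, 0, -0.1), lo=0.5, hi=21
            ),
            "resp_rate": ContinuousSpec(
                40, (32, 50), shifts=(8, 7, 0, -1, -2), lo=15, hi=120,
                severity_loading=0.5
            ),
            "heart_rate": ContinuousSpec(
                142, (126, 158), shifts=(10, 8, 0, -2, -3), lo=60, hi=240,
                severity_loading=0.5
            ),
            "spo2_pct": ContinuousSpec(
                98, (97, 100), shifts=(-2, -1.5, 0, -0.3, -0.3), lo=70, hi=100,
                severity_loading=-0.4
            ),
            "crp_mg_l": ContinuousSpec(
                16, (7, 42), "lognormal", shifts=(1.7, 1.9, 0, -0.2, -0.35),
                lo=0.5, hi=600
            ),
        },
        binaries={
            "ill_appearance": BinarySpec(0.23, (1.2, 1.0, 0, -0.3, -0.5)),
            "dyspnoea": BinarySpec(0.43, (0.6, 0.5, 0, 0.2, 0.3)),
            "retractions": BinarySpec(0.64, (0.5, 0.5, 0, 0.3, 0.4)),
            "nasal_flaring": BinarySpec(0.50, (0.5, 0.4, 0, 0.2, 0.2)),
            "crackles": BinarySpec(0.24, (0.8, 0.7, 0, -0.2, -0.3)),
            "focal_rales": BinarySpec(0.44, (0.7, 0.6, 0, -0.2, -0.3)),
            "decreased_breath_sounds": BinarySpec(0.09, (0.8, 0.8, 0, -0.2, -0.3)),
            "wheeze": BinarySpec(0.35, (-0.5, -0.5, 0, 0.5, 0.7)),
            "chest_pain": BinarySpec(0.10, (0.5, 0.5, 0, 0, 0)),
            "cap_refill_prolonged": BinarySpec(0.19, (0.8, 0.6, 0, -0.2, -0.3)),
            "something_wrong": BinarySpec(0.20, (1.0, 0.8, 0, -0.3, -0.4)),
        },
        missingness={
            "temperature_c": 0.04,
            "fever_duration_days": 0.05,
            "resp_rate": 65 / 248,
            "heart_rate": 41 / 248,
            "spo2_pct": 0.08,
            "ill_appearance": 99 / 248,
            "dyspnoea": 0.0,
            "retractions": 141 / 248,
            "nasal_flaring": 190 / 248,
            "crackles": 121 / 248,
            "focal_rales": 97 / 248,
            "decreased_breath_sounds": 112 / 248,
            "wheeze": 0.30,
            "chest_pain": 0.60,
            "cap_refill_prolonged": 195 / 248,
            "something_wrong": 0.30,
        },
        crp_measured_fraction=94 / 248,
        rx_rates=(0.85, 0.80, 0.25, 0.08, 0.05),
        male_fraction=148 / 248,
        effect_size=effect_size,
        seed=seed,
        target_rates={"tachypnea": 0.44, "tachycardia": 0.32, "antibiotics": 51 / 248},
    )


def _coventry_profile(n: int = 301, effect_size: float = 1.0, seed: int = 0) -> CohortProfile:
    return CohortProfile(
        name="coventry_like",
        n=n,
        category_mixture=(37 / 301, 16 / 301, 122 / 301, 72 / 301, 54 / 301),
        continuous={
            "age_months": ContinuousSpec(19, (12, 31), "lognormal", lo=3, hi=60),
            "temperature_c": ContinuousSpec(
                38.2, (37.5, 39.1), shifts=(0.5, 0.5, 0, -0.1, -0.15),
                lo=35, hi=42, severity_loading=0.4
            ),
            "fever_duration_days": ContinuousSpec(
                3, (2, 4), "lognormal", shifts=(0.2, 0.2, 0, 0, -0.1), lo=0.5, hi=21
            ),
            "resp_rate": ContinuousSpec(
                44, (35, 54), shifts=(8, 7, 0, -1, -2), lo=15, hi=120,
                severity_loading=0.5
            ),
            "heart_rate": ContinuousSpec(
                155, (138, 172), shifts=(10, 8, 0, -2, -3), lo=60, hi=240,
                severity_loading=0.5
            ),
            "spo2_pct": ContinuousSpec(
                97, (95, 98), shifts=(-2, -1.5, 0, -0.3, -0.3), lo=70, hi=100,
                severity_loading=-0.4
            ),
            "crp_mg_l": ContinuousSpec(
                45, (19, 122), "lognormal", shifts=(1.2, 1.4, 0, -0.3, -0.45),
                lo=0.5, hi=600
            ),
        },
        binaries={
            "ill_appearance": BinarySpec(0.003, (1.2, 1.0, 0, -0.3, -0.5)),
            "dyspnoea": BinarySpec(0.27, (0.6, 0.5, 0, 0.2, 0.3)),
            "retractions": BinarySpec(0.60, (0.5, 0.5, 0, 0.3, 0.4)),
            "nasal_flaring": BinarySpec(0.45, (0.5, 0.4, 0, 0.2, 0.2)),
            "crackles": BinarySpec(0.25, (0.8, 0.7, 0, -0.2, -0.3)),
            "focal_rales": BinarySpec(0.40, (0.7, 0.6, 0, -0.2, -0.3)),
            "decreased_breath_sounds": BinarySpec(0.10, (0.8, 0.8, 0, -0.2, -0.3)),
            "wheeze": BinarySpec(0.35, (-0.5, -0.5, 0, 0.5, 0.7)),
            "chest_pain": BinarySpec(0.10, (0.5, 0.5, 0, 0, 0)),
            "cap_refill_prolonged": BinarySpec(0.31, (0.8, 0.6, 0, -0.2, -0.3)),
            "something_wrong": BinarySpec(0.20, (1.0, 0.8, 0, -0.3, -0.4)),
        },
        missingness={
            "temperature_c": 0.02,
            "fever_duration_days": 1.0,
            "resp_rate": 43 / 301,
            "heart_rate": 7 / 301,
            "spo2_pct": 0.05,
            "ill_appearance": 0.0,
            "dyspnoea": 0.0,
            "retractions": 1.0,
            "nasal_flaring": 1.0,
            "crackles": 1.0,
            "focal_rales": 1.0,
            "decreased_breath_sounds": 1.0,
            "wheeze": 0.30,
            "chest_pain": 1.0,
            "cap_refill_prolonged": 114 / 301,
            "something_wrong": 1.0,
        },
        crp_measured_fraction=109 / 301,
        rx_rates=(0.90, 0.85, 0.40, 0.12, 0.08),
        male_fraction=174 / 301,
        effect_size=effect_size,
        seed=seed,
        target_rates={"tachypnea": 0.60, "tachycardia": 0.65, "antibiotics": 105 / 301},
    )


_PRESETS = {"rotterdam_like": _rotterdam_profile, "coventry_like": _coventry_profile}


def preset(
    name: str, n: int | None = None, effect_size: float = 1.0, seed: int = 0
) -> CohortProfile:
    """Named cohort profile with published marginal targets.

    ``rotterdam_like`` defaults to n=248, ``coventry_like`` to n=301.
    """
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(_PRESETS)}")
    profile = _PRESETS[name](effect_size=effect_size, seed=seed)
    if n is not None:
        profile = replace(profile, n=n)
    return profile
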