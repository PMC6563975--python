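"""Threshold-based harm/benefit analysis for antibiotic prescribing.

For a probability model and a risk threshold, children with predicted risk
strictly below the threshold form the low-risk group in whom antibiotics
would be withheld. Benefit is the resulting reduction in antibiotic
prescriptions; harm (under-treatment) counts children with a bacterial
outcome (ordinal categories 1–2) who actually received antibiotics but
whom the policy would label low-risk. No counterfactual outcome modelling
is attempted — both quantities are counts of observable subgroups.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .metrics import round_half_away

DEFAULT_THRESHOLDS = (0.10, 0.15)


@dataclass(frozen=True)
class ThresholdReport:
    """Observed vs threshold-guided care at one risk threshold."""

    model_name: str
    threshold: float
    n: int
    n_low_risk: int
    observed_rx: int
    expected_rx: int
    undertreated: int

    @property
    def pct_low_risk(self) -> int:
        return int(round_half_away(100.0 * self.n_low_risk / self.n))

    @property
    def pct_observed_rx(self) -> int:
        return int(round_half_away(100.0 * self.observed_rx / self.n))

    @property
    def pct_expected_rx(self) -> int:
        return int(round_half_away(100.0 * self.expected_rx / self.n))

    @property
    def pct_undertreated(self) -> int:
        return int(round_half_away(100.0 * self.undertreated / self.n))

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(
            pct_low_risk=self.pct_low_risk,
            pct_observed_rx=self.pct_observed_rx,
            pct_expected_rx=self.pct_expected_rx,
            pct_undertreated=self.pct_undertreated,
        )
        return d


def low_risk_group(risks, threshold: float, comparator: str = "lt"):
    """Boolean mask of children below the threshold, plus the count.

    "Below threshold" is strict by default (a risk exactly at the
    threshold is not low-risk); ``comparator="le"`` is available for
    sensitivity analysis.
    """
    risks = np.asarray(risks, dtype=float)
    if np.any((risks < 0) | (risks > 1)):
        raise ValueError("risks must lie in [0, 1]")
    mask = risks < threshold if comparator == "lt" else risks <= threshold
    return mask, int(mask.sum())


def expected_prescriptions(rx, low_mask) -> int:
    """Prescriptions remaining if antibiotics are withheld below threshold.

    Equals observed prescriptions minus those withheld in the low-risk
    group, i.e. the count of treated children outside the low-risk group.
    """
    rx = np.asarray(rx, dtype=bool)
    low_mask = np.asarray(low_mask, dtype=bool)
    if rx.shape != low_mask.shape:
        raise ValueError("rx and low-risk mask must align")
    return int((rx & ~low_mask).sum())


def undertreatment(low_mask, bacterial, rx) -> int:
    """Children with bacterial infection, actually treated, labelled low-risk."""
    low_mask = np.asarray(low_mask, dtype=bool)
    bacterial = np.asarray(bacterial, dtype=bool)
    rx = np.asarray(rx, dtype=bool)
    if not (low_mask.shape == bacterial.shape == rx.shape):
        raise ValueError("masks must align")
    return int((low_mask & bacterial & rx).sum())


def threshold_report(
    model_name: str,
    risks,
    rx,
    bacterial,
    thresholds=DEFAULT_THRESHOLDS,
    comparator: str = "lt",
) -> list[ThresholdReport]:
    """One harm/benefit report per threshold."""
    risks = np.asarray(risks, dtype=float)
    rx = np.asarray(rx, dtype=bool)
    bacterial = np.asarray(bacterial, dtype=bool)
    reports = []
    for t in thresholds:
        mask, n_low = low_risk_group(risks, t, comparator=comparator)
        reports.append(
            ThresholdReport(
                model_name=model_name,
                threshold=float(t),
                n=int(risks.size),
                n_low_risk=n_low,
                observed_rx=int(rx.sum()),
                expected_rx=expected_prescriptions(rx, mask),
                undertreated=undertreatment(mask, bacterial, rx),
            )
        )
    return reports
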