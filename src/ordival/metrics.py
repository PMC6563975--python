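"""Discrimination and diagnostic-accuracy metrics.

The central statistic is the ordinal c-statistic (ORC): the AUC
generalised to an ordinal outcome, interpretable as the probability that
two cases drawn from different, randomly selected outcome categories are
ranked correctly by the model's score. Two estimators are provided:

* ``unweighted_pairs`` (default) — the simple mean of the pairwise AUCs
  over all observed category pairs i<j, i.e. category pairs are selected
  uniformly at random;
* ``pooled_pairs`` — the concordant fraction over all cross-category
  record pairs, which weights category pairs by their sizes.

For two categories both reduce to the ordinary Mann–Whitney AUC.
Orientation: lower category number = more bacterial = higher expected
score, so a perfect bacterial-risk score has ORC 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.stats import rankdata

from .missing_data import PooledEstimate

ORC_CRITERION = 0.55  # pooled ORC at or above this counts as performing well


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class PerformanceSummary:
    """Per-model discrimination summary against the 5-category standard."""

    model_name: str
    orc: PooledEstimate
    pairwise_auc: dict[tuple[int, int], float]
    n_per_category: np.ndarray
    orc_pooled_pairs: PooledEstimate | None = None
    is_rule_model: bool = False


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention printed tables follow)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pairwise_auc(scores_a, scores_b) -> float:
    """P(score from the more-bacterial category a > score from b), ties = 1/2.

    Equals the Mann–Whitney U statistic scaled to [0, 1]; computed with
    midranks so it is exact under ties and O(n log n).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("pairwise_auc requires non-empty score lists")
    ranks = rankdata(np.concatenate([a, b]))
    u = ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0
    return float(u / (a.size * b.size))


def orc(
    scores,
    categories,
    weighting: str = "unweighted_pairs",
) -> tuple[float, dict[tuple[int, int], float]]:
    """Ordinal c-statistic of a bacterial-risk score.

    Parameters
    ----------
    scores
        Per-record risk of bacterial infection (any monotone score works:
        the statistic is rank-based).
    categories
        Per-record ordinal category, 1 (bacterial) .. 5 (viral).
    weighting
        ``unweighted_pairs`` or ``pooled_pairs`` (see module docstring).

    Returns
    -------
    value, pairwise
        The ORC and the dict of pairwise AUCs keyed by (i, j), i < j,
        oriented so that concordance means the category-i record scores
        higher.
    """
    scores = np.asarray(scores, dtype=float)
    categories = np.asarray(categories, dtype=int)
    if scores.shape != categories.shape:
        raise ValueError("scores and categories must align")
    present = np.unique(categories)
    if present.size < 2:
        raise ValueError("ORC needs at least two outcome categories present")
    if weighting not in ("unweighted_pairs", "pooled_pairs"):
        raise ValueError(f"unknown weighting {weighting!r}")

    by_cat = {int(c): scores[categories == c] for c in present}
    pairwise: dict[tuple[int, int], float] = {}
    num, den = 0.0, 0.0
    for idx, i in enumerate(present):
        for j in present[idx + 1 :]:
            auc = pairwise_auc(by_cat[int(i)], by_cat[int(j)])
            pairwise[(int(i), int(j))] = auc
            w = (
                1.0
                if weighting == "unweighted_pairs"
                else by_cat[int(i)].size * by_cat[int(j)].size
            )
            num += w * auc
            den += w
    return num / den, pairwise


def binary_metrics(counts: ConfusionCounts) -> tuple[float, float]:
    """Sensitivity and specificity as fractions."""
    if counts.tp + counts.fn == 0:
        raise ZeroDivisionError("no positive cases: sensitivity undefined")
    if counts.tn + counts.fp == 0:
        raise ZeroDivisionError("no negative cases: specificity undefined")
    return (
        counts.tp / (counts.tp + counts.fn),
        counts.tn / (counts.tn + counts.fp),
    )


def lr_positive(sens: float, spec: float) -> float:
    """Positive likelihood ratio sens/(1-spec); inf when spec == 1."""
    if spec >= 1.0:
        return float("inf")
    return sens / (1.0 - spec)


def lr_negative(sens: float, spec: float) -> float:
    """Negative likelihood ratio (1-sens)/spec."""
    if spec <= 0.0:
        raise ZeroDivisionError("LR- undefined for specificity 0")
    return (1.0 - sens) / spec


def prevalence(k: int, n: int) -> float:
    """Prevalence as a percentage, 100*k/n."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    return 100.0 * k / n


def rule_class_crosstab(risk_classes, categories) -> dict[int, dict[str, int]]:
    """Category-by-class counts for rule (high/low) models."""
    out: dict[int, dict[str, int]] = {}
    for cat in range(1, 6):
        mask = np.asarray(categories) == cat
        cls = np.asarray(risk_classes)[mask]
        out[cat] = {
            "high": int((cls == "high").sum()),
            "low": int((cls == "low").sum()),
        }
    return out
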