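import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from ordival.metrics import (
    ConfusionCounts,
    binary_metrics,
    lr_negative,
    lr_positive,
    orc,
    pairwise_auc,
    prevalence,
    round_half_away,
)


def brute_force_orc(scores, categories, weighting):
    """Independent oracle: exhaustive enumeration over all cross-category
    record pairs / category-pair means."""
    scores = np.asarray(scores, float)
    categories = np.asarray(categories, int)
    cats = sorted(set(categories.tolist()))
    aucs, weights = [], []
    for i, j in itertools.combinations(cats, 2):
        a = scores[categories == i]
        b = scores[categories == j]
        conc = sum(
            1.0 if x > y else (0.5 if x == y else 0.0) for x in a for y in b
        )
        aucs.append(conc / (len(a) * len(b)))
        weights.append(len(a) * len(b))
    if weighting == "unweighted_pairs":
        return float(np.mean(aucs))
    return float(np.average(aucs, weights=weights))


class TestPairwiseAuc:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([0.9], [0.1], 1.0),
            ([0.5], [0.5], 0.5),
            ([0.8, 0.4], [0.6, 0.2], 0.75),  # 3 concordant of 4 pairs
        ],
    )
    def test_small_cases(self, a, b, expected):
        assert pairwise_auc(a, b) == pytest.approx(expected)

    def test_complement_symmetry_without_ties(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(9), rng.random(7)
        assert pairwise_auc(a, b) + pairwise_auc(b, a) == pytest.approx(1.0)

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            pairwise_auc([], [0.5])


class TestOrc:
    def test_perfect_ordering_scores_one(self):
        cats = np.repeat([1, 2, 3, 4, 5], 3)
        scores = np.linspace(1.0, 0.0, cats.size)  # strictly decreasing
        for weighting in ("unweighted_pairs", "pooled_pairs"):
            assert orc(scores, cats, weighting)[0] == pytest.approx(1.0)

    def test_constant_scores_give_half(self):
        cats = np.repeat([1, 3, 5], 4)
        assert orc(np.full(cats.size, 0.3), cats)[0] == pytest.approx(0.5)

    def test_single_category_rejected(self):
        with pytest.raises(ValueError):
            orc([0.1, 0.2], [3, 3])

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_exhaustive_pair_oracle(self, data):
        n = data.draw(st.integers(4, 12))
        cats = data.draw(
            st.lists(st.integers(1, 3), min_size=n, max_size=n).filter(
                lambda c: len(set(c)) >= 2
            )
        )
        scores = data.draw(
            st.lists(
                st.floats(0, 1, allow_nan=False, width=32), min_size=n, max_size=n
            )
        )
        for weighting in ("unweighted_pairs", "pooled_pairs"):
            got, _ = orc(scores, cats, weighting)
            assert got == pytest.approx(
                brute_force_orc(scores, cats, weighting), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        cats = rng.integers(1, 6, size=60)
        scores = rng.random(60)
        base, _ = orc(scores, cats)
        for f in (lambda s: s**3, np.expm1, lambda s: 5 * s - 2):
            assert orc(f(scores), cats)[0] == pytest.approx(base, abs=1e-12)

    def test_reversing_category_order_complements(self):
        rng = np.random.default_rng(8)
        cats = rng.integers(1, 6, size=80)
        scores = rng.random(80)
        for weighting in ("unweighted_pairs", "pooled_pairs"):
            fwd, _ = orc(scores, cats, weighting)
            rev, _ = orc(scores, 6 - cats, weighting)
            assert fwd + rev == pytest.approx(1.0, abs=1e-12)

    def test_two_categories_reduce_to_binary_auc(self):
        rng = np.random.default_rng(12)
        cats = rng.choice([1, 4], size=100)
        scores = rng.random(100)
        reference = roc_auc_score(cats == 1, scores)
        for weighting in ("unweighted_pairs", "pooled_pairs"):
            assert orc(scores, cats, weighting)[0] == pytest.approx(
                reference, abs=1e-12
            )

    def test_null_association_centres_on_half(self):
        """With no predictor-outcome association, mean ORC over 200 seeds
        stays within 3 SE of 0.5."""
        values = []
        for seed in range(200):
            rng = np.random.default_rng(1000 + seed)
            cats = np.concatenate([np.repeat([1, 2, 3, 4, 5], 8)])
            scores = rng.random(cats.size)
            values.append(orc(scores, cats)[0])
        se = np.std(values, ddof=1) / np.sqrt(len(values))
        assert abs(np.mean(values) - 0.5) <= 3 * se


class TestBinaryMetrics:
    def test_sens_spec_from_counts(self):
        sens, spec = binary_metrics(ConfusionCounts(tp=28, fp=107, fn=16, tn=359))
        assert sens == pytest.approx(28 / 44)
        assert spec == pytest.approx(359 / 466)

    def test_balanced_and_degenerate_cases(self):
        sens, _ = binary_metrics(ConfusionCounts(tp=5, fp=3, fn=5, tn=7))
        assert sens == pytest.approx(0.5)
        _, spec = binary_metrics(ConfusionCounts(tp=5, fp=0, fn=5, tn=7))
        assert spec == 1.0

    def test_zero_denominators_rejected(self):
        with pytest.raises(ZeroDivisionError):
            binary_metrics(ConfusionCounts(tp=0, fp=3, fn=0, tn=7))
        with pytest.raises(ZeroDivisionError):
            binary_metrics(ConfusionCounts(tp=2, fp=0, fn=3, tn=0))


class TestLikelihoodRatios:
    """Published sensitivity/specificity pairs must reproduce the printed
    likelihood ratios at their printed precision."""

    @pytest.mark.parametrize(
        "sens,spec,lr_pos,lr_neg,dp_pos,dp_neg",
        [
            (0.636, 0.77, 2.8, 0.5, 1, 1),    # any-of rule model
            (0.941, 0.446, 1.7, 0.13, 1, 2),  # dyspnoea rule, validation 1
            (0.658, 0.431, 1.16, 0.79, 2, 2), # dyspnoea rule, validation 3
        ],
    )
    def test_printed_lr_pairs(self, sens, spec, lr_pos, lr_neg, dp_pos, dp_neg):
        assert round_half_away(lr_positive(sens, spec), dp_pos) == lr_pos
        assert round_half_away(lr_negative(sens, spec), dp_neg) == lr_neg

    def test_high_sens_spec_pair_gives_tiny_lr_negative(self):
        assert round_half_away(lr_negative(0.938, 0.932), 2) == 0.07

    def test_perfect_specificity_signals_infinite_lr_positive(self):
        assert lr_positive(0.9, 1.0) == float("inf")

    def test_perfect_sensitivity_gives_zero_lr_negative(self):
        assert lr_negative(1.0, 0.5) == 0.0


class TestPrevalence:
    @pytest.mark.parametrize(
        "k,n,ndigits,expected",
        [(44, 510, 1, 8.6), (51, 248, 0, 21.0), (0, 10, 0, 0.0)],
    )
    def test_printed_prevalences(self, k, n, ndigits, expected):
        assert round_half_away(prevalence(k, n), ndigits) == expected

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            prevalence(1, 0)
        with pytest.raises(ValueError):
            prevalence(5, 4)


class TestRounding:
    def test_half_away_from_zero(self):
        assert round_half_away(0.5) == 1.0
        assert round_half_away(2.765, 2) == 2.77
        assert round_half_away(14.11) == 14.0
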