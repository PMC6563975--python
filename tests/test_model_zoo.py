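import math

import numpy as np
import pandas as pd
import pytest

from ordival.model_zoo import (
    ModelSpec,
    ModelSpecError,
    Term,
    UnresolvedPredictorError,
    builtin_model_names,
    evaluate_logistic_model,
    evaluate_logistic_model_frame,
    evaluate_rule_model,
    load_builtin_model,
    load_model_spec,
    predictor_availability,
    truncate_crp,
)

from conftest import make_cohort


class TestTruncateCrp:
    @pytest.mark.parametrize("value,expected", [(300, 225), (225, 225), (16, 16)])
    def test_cap(self, value, expected):
        assert truncate_crp(value) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            truncate_crp(-5)


class TestSpecLoading:
    def test_all_builtin_models_load(self):
        names = builtin_model_names()
        assert {"mahabee", "vandenbruel", "neuman", "lynch", "oostenbrink",
                "nijman", "irwin"} <= set(names)
        for name in names:
            spec = load_builtin_model(name)
            assert spec.predictors

    def test_vandenbruel_is_two_predicate_rule(self):
        spec = load_builtin_model("vandenbruel")
        assert spec.form == "rule_tree" and len(spec.predictors) == 2

    def test_nijman_is_eleven_predictor_logistic(self):
        spec = load_builtin_model("nijman")
        assert spec.form == "logistic" and len(spec.predictor_variables) == 11

    def test_unknown_variable_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text(
            "name: bad\nform: logistic\npredictors:\n"
            "  - {variable: shoe_size, coefficient: 1.0}\n"
        )
        with pytest.raises(ModelSpecError, match="shoe_size"):
            load_model_spec(path)

    def test_logistic_term_without_coefficient_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text(
            "name: bad\nform: logistic\npredictors:\n  - {variable: crp_mg_l}\n"
        )
        with pytest.raises(ModelSpecError, match="coefficient"):
            load_model_spec(path)

    def test_rule_term_without_predicate_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text(
            "name: bad\nform: rule_tree\npredictors:\n  - {variable: dyspnoea}\n"
        )
        with pytest.raises(ModelSpecError, match="predicate"):
            load_model_spec(path)


class TestRuleModels:
    def test_mahabee_any_of(self):
        spec = load_builtin_model("mahabee")
        base = dict(resp_rate=40.0, spo2_pct=99.0, nasal_flaring=False)
        assert evaluate_rule_model(spec, dict(base, age_months=20.0)) == "high"  # age>=12
        assert evaluate_rule_model(spec, dict(base, age_months=6.0)) == "low"
        # nasal flaring only raises risk in infants under 12 months
        assert evaluate_rule_model(
            spec, dict(base, age_months=6.0, nasal_flaring=True)) == "high"
        assert evaluate_rule_model(
            spec, dict(age_months=6.0, resp_rate=55.0, spo2_pct=99.0,
                       nasal_flaring=False)) == "high"

    def test_vandenbruel_dyspnoea_or_gestalt(self):
        spec = load_builtin_model("vandenbruel")
        assert evaluate_rule_model(
            spec, dict(dyspnoea=False, something_wrong=False)) == "low"
        assert evaluate_rule_model(
            spec, dict(dyspnoea=True, something_wrong=False)) == "high"
        assert evaluate_rule_model(
            spec, dict(dyspnoea=False, something_wrong=True)) == "high"

    @pytest.mark.parametrize("spo2,expected", [(91, "high"), (92, "high"), (95, "low")])
    def test_neuman_first_split(self, spo2, expected):
        assert evaluate_rule_model(
            load_builtin_model("neuman"), dict(spo2_pct=float(spo2))) == expected

    def test_predicate_order_is_irrelevant(self):
        spec = load_builtin_model("vandenbruel")
        flipped = ModelSpec(
            name=spec.name, form=spec.form, predictors=spec.predictors[::-1])
        record = dict(dyspnoea=True, something_wrong=False)
        assert evaluate_rule_model(spec, record) == evaluate_rule_model(flipped, record)

    def test_unresolved_predictor_is_named(self):
        spec = load_builtin_model("vandenbruel")
        with pytest.raises(UnresolvedPredictorError, match="dyspnoea"):
            evaluate_rule_model(spec, dict(something_wrong=False))


def _logistic(name, terms, intercept=0.0):
    return ModelSpec(name=name, form="logistic", predictors=tuple(terms),
                     intercept=intercept)


class TestLogisticModels:
    def test_closed_form_risks(self):
        null = _logistic("null", [Term("crp_mg_l", coefficient=0.0)], intercept=0.0)
        assert evaluate_logistic_model(null, dict(crp_mg_l=50.0)) == pytest.approx(0.5)
        odds9 = _logistic("odds9", [Term("crp_mg_l", coefficient=0.0)],
                          intercept=math.log(9))
        assert evaluate_logistic_model(odds9, dict(crp_mg_l=1.0)) == pytest.approx(0.9)

    def test_single_binary_term(self):
        spec = _logistic("one", [Term("dyspnoea", coefficient=1.0)], intercept=-1.0)
        assert evaluate_logistic_model(spec, dict(dyspnoea=True)) == pytest.approx(0.5)
        assert evaluate_logistic_model(spec, dict(dyspnoea=False)) == pytest.approx(
            1 / (1 + math.e), rel=1e-6)

    def test_risk_increasing_in_positive_coefficient_predictor(self):
        spec = load_builtin_model("oostenbrink")
        lo = dict(ill_appearance=False, tachypnea=False, spo2_pct=98.0, crp_mg_l=10.0)
        risks = [evaluate_logistic_model(spec, dict(lo, crp_mg_l=c))
                 for c in (5.0, 20.0, 80.0, 200.0)]
        assert risks == sorted(risks) and len(set(risks)) == 4

    def test_truncation_makes_extreme_crp_equivalent(self):
        spec = load_builtin_model("oostenbrink")
        base = dict(ill_appearance=False, tachypnea=False, spo2_pct=98.0)
        assert evaluate_logistic_model(spec, dict(base, crp_mg_l=300.0)) == \
            evaluate_logistic_model(spec, dict(base, crp_mg_l=225.0))

    def test_agrees_with_bruteforce_linear_predictor(self):
        """Vectorised evaluation matches a per-record recomputation to 1e-12
        on random specs and records."""
        rng = np.random.default_rng(7)
        variables = ["age_months", "temperature_c", "resp_rate", "spo2_pct",
                     "crp_mg_l", "fever_duration_days"]
        for _ in range(20):
            k = rng.integers(1, len(variables) + 1)
            chosen = list(rng.choice(variables, size=k, replace=False))
            coefs = rng.normal(size=k)
            centers = rng.normal(size=k)
            intercept = float(rng.normal())
            spec = _logistic(
                "rand",
                [Term(v, coefficient=float(c), center=float(ctr))
                 for v, c, ctr in zip(chosen, coefs, centers)],
                intercept=intercept,
            )
            frame = pd.DataFrame(
                {v: np.abs(rng.normal(50, 20, size=8)) for v in variables}
            ).astype("Float64")
            got = evaluate_logistic_model_frame(spec, frame)
            for i in range(8):
                lp = intercept
                for v, c, ctr in zip(chosen, coefs, centers):
                    x = float(frame[v].iloc[i])
                    if v == "crp_mg_l":
                        x = min(x, 225.0)
                    lp += c * (x - ctr)
                assert got.iloc[i] == pytest.approx(1 / (1 + math.exp(-lp)), abs=1e-12)


class TestAvailability:
    def test_exactly_half_is_excluded(self):
        # Lynch with only temperature and resp-rate-derived tachypnea: 2/4
        cohort = make_cohort([
            dict(patient_id="a", working_diagnosis="pneumonia",
                 temperature_c=38.5, resp_rate=44.0, age_months=20.0),
        ])
        fraction, include = predictor_availability(load_builtin_model("lynch"), cohort)
        assert fraction == pytest.approx(0.5) and not include

    def test_all_available_is_included(self, tiny_cohort):
        cohort = tiny_cohort.copy()
        cohort.data["spo2_pct"] = 98.0
        fraction, include = predictor_availability(
            load_builtin_model("neuman"), cohort)
        assert fraction == 1.0 and include

    def test_derivation_constants_do_not_count_as_available(self):
        # Irwin: CRP, resp rate and air entry present; resistin and
        # procalcitonin only via derivation constants -> 3/5, included
        cohort = make_cohort([
            dict(patient_id="a", working_diagnosis="pneumonia", crp_mg_l=30.0,
                 resp_rate=40.0, decreased_breath_sounds=False, age_months=15.0),
        ])
        fraction, include = predictor_availability(load_builtin_model("irwin"), cohort)
        assert fraction == pytest.approx(0.6) and include
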