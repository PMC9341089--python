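"""Model registry: coefficients, predictor derivation, risks and scores."""

import math

import numpy as np
import pytest
import yaml

from ckdval.models import (KEARNS_AGE_CENTERING, MODEL_NAMES,
                           IncompleteRecordError, PersonProfile,
                           builtin_models, builtin_score_tables, classify,
                           derive_predictors, linear_predictor,
                           models_from_config, models_to_config, predict_risk,
                           score)

from conftest import ALL_FLAGS, make_derived


class TestRegistry:
    def test_six_models_with_printed_parameter_counts(self, registry):
        expected = {"scored": 9, "modified_scored": 7, "kearns": 5,
                    "kshirsagar": 8, "kwon": 7, "thakkinstian": 4}
        assert set(registry) == set(MODEL_NAMES)
        assert {n: s.n_parameters for n, s in registry.items()} == expected

    def test_intercepts(self, registry):
        assert registry["scored"].intercept == -5.40
        assert registry["modified_scored"].intercept == -5.38
        assert registry["kearns"].intercept == -3.63
        assert registry["kshirsagar"].intercept == -3.30
        assert registry["kwon"].intercept == -6.53

    def test_kearns_age_centering_constant(self, registry):
        assert registry["kearns"].age_centering == KEARNS_AGE_CENTERING == 46.72

    def test_thakkinstian_intercept_candidates(self):
        assert builtin_models()["thakkinstian"].intercept == -3.3
        assert builtin_models("published")["thakkinstian"].intercept == -2.8
        assert builtin_models(-3.0)["thakkinstian"].intercept == -3.0

    def test_anemia_and_diabetes_rules(self, registry):
        assert registry["kwon"].anemia_rule == "hb_lt_12_f_13_m"
        for name in ("scored", "modified_scored", "kshirsagar"):
            assert registry[name].anemia_rule == "hb_lt_12_all"
            assert registry[name].diabetes_rule == "selfreport_only"
        assert registry["thakkinstian"].diabetes_rule == "selfreport_or_med"


class TestDerivePredictors:
    def _profile(self, **kw):
        base = dict(age=60.0, sex="male", systolic_bp=120.0, diastolic_bp=80.0,
                    antihypertensive_med=False, diabetes_selfreport=False,
                    antidiabetic_med=False, hemoglobin=14.0, ihd_history=False,
                    stroke_history=False, heart_failure_history=False,
                    pvd_history=False, proteinuria_selfreport=False,
                    kidney_stones_history=False)
        base.update(kw)
        return PersonProfile(**base)

    @pytest.mark.parametrize("sbp,dbp,med,expected", [
        (145.0, 85.0, False, True),   # systolic alone suffices
        (140.0, 80.0, False, True),   # boundary is inclusive ('at least 140')
        (139.9, 89.9, False, False),
        (120.0, 90.0, False, True),
        (120.0, 80.0, True, True),    # medication alone suffices
    ])
    def test_hypertension_definition(self, registry, sbp, dbp, med, expected):
        p = self._profile(systolic_bp=sbp, diastolic_bp=dbp,
                          antihypertensive_med=med)
        d = derive_predictors(p, registry["scored"])
        assert d.hypertension is expected

    @pytest.mark.parametrize("hb,sex,model,expected", [
        (12.5, "male", "kwon", True),      # sex-specific < 13 for men
        (12.5, "male", "scored", False),   # common rule < 12
        (12.0, "female", "kwon", False),   # strict inequality at 12
        (12.0, "female", "scored", False),
        (11.9, "male", "scored", True),
    ])
    def test_anemia_rules(self, registry, hb, sex, model, expected):
        d = derive_predictors(self._profile(hemoglobin=hb, sex=sex),
                              registry[model])
        assert d.anemia is expected

    def test_diabetes_rule_medication_counts_for_kwon_only(self, registry):
        p = self._profile(diabetes_selfreport=False, antidiabetic_med=True)
        assert derive_predictors(p, registry["kwon"]).diabetes is True
        assert derive_predictors(p, registry["scored"]).diabetes is False

    def test_acr_threshold_when_no_selfreport(self, registry):
        p = self._profile(proteinuria_selfreport=None, acr=30.0)
        assert derive_predictors(p, registry["scored"]).proteinuria is True
        p = self._profile(proteinuria_selfreport=None, acr=29.9)
        assert derive_predictors(p, registry["scored"]).proteinuria is False

    def test_explicit_flags_fill_missing_measurements(self, registry):
        p = PersonProfile(age=60.0, sex="female", hypertension_known=True,
                          anemia_known=False, diabetes_selfreport=False,
                          ihd_history=False, stroke_history=False,
                          heart_failure_history=False, pvd_history=False,
                          proteinuria_selfreport=False)
        d = derive_predictors(p, registry["modified_scored"])
        assert d.hypertension is True and d.anemia is False

    def test_incomplete_record_lists_missing_predictors(self, registry):
        p = PersonProfile(age=60.0, sex="male", diabetes_selfreport=False)
        with pytest.raises(IncompleteRecordError) as exc:
            derive_predictors(p, registry["scored"])
        assert "anemia" in exc.value.missing
        assert "hypertension" in exc.value.missing

    def test_kidney_stones_required_only_by_thakkinstian(self, registry):
        p = self._profile(kidney_stones_history=None)
        derive_predictors(p, registry["scored"])  # fine
        with pytest.raises(IncompleteRecordError):
            derive_predictors(p, registry["thakkinstian"])

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            PersonProfile(age=-1.0, sex="male")
        with pytest.raises(ValueError):
            PersonProfile(age=60.0, sex="x")
        with pytest.raises(ValueError):
            PersonProfile(age=60.0, sex="male", hemoglobin=0.0)


class TestLinearPredictorAndRisk:
    def test_scored_hand_sum(self, registry):
        d = make_derived(75, female=True, hypertension=True, diabetes=True,
                         proteinuria=True, anemia=True)
        lp = linear_predictor(registry["scored"], d)
        assert lp == pytest.approx(-5.40 + 3.23 + 0.29 + 0.45 + 0.44
                                   + 0.83 + 0.93, abs=1e-12)
        assert lp == pytest.approx(0.77, abs=1e-9)

    def test_intercept_only_case(self, registry):
        d = make_derived(45, female=False)
        assert linear_predictor(registry["scored"], d) == pytest.approx(-5.40)

    def test_kearns_centered_age_vanishes(self, registry):
        d = make_derived(46.72, female=False)
        assert linear_predictor(registry["kearns"], d) == pytest.approx(-3.63)

    def test_kearns_age_interaction_addons_only_below_50(self, registry):
        kearns = registry["kearns"]
        young_ht = make_derived(45, hypertension=True)
        young_no = make_derived(45)
        old_ht = make_derived(55, hypertension=True)
        old_no = make_derived(55)
        assert (linear_predictor(kearns, young_ht)
                - linear_predictor(kearns, young_no)) == pytest.approx(0.74 + 0.56)
        assert (linear_predictor(kearns, old_ht)
                - linear_predictor(kearns, old_no)) == pytest.approx(0.74)

    def test_risk_is_inverse_logit_of_lp(self, registry):
        rng = np.random.default_rng(0)
        for _ in range(50):
            name = rng.choice(MODEL_NAMES)
            d = make_derived(float(rng.uniform(40, 80)), bool(rng.random() < 0.5),
                             **{f: bool(rng.random() < 0.3) for f in ALL_FLAGS})
            lp = linear_predictor(registry[name], d)
            assert predict_risk(registry[name], d) == pytest.approx(
                1.0 / (1.0 + math.exp(-lp)), rel=1e-14)

    def test_zero_lp_gives_half(self, registry):
        spec = registry["thakkinstian"]
        # age >= 70 (2.1) + ht (0.8) + dm (0.9) - stones absent: lp = -3.3+3.8
        d = make_derived(72, hypertension=True, diabetes=True)
        import dataclasses
        spec2 = dataclasses.replace(spec, intercept=-3.8)
        assert predict_risk(spec2, d) == pytest.approx(0.5)

    def test_monotone_in_positive_coefficients(self, registry):
        rng = np.random.default_rng(1)
        for _ in range(100):
            name = rng.choice(MODEL_NAMES)
            spec = registry[name]
            flags = {f: bool(rng.random() < 0.4) for f in ALL_FLAGS}
            age = float(rng.uniform(40, 80))
            fem = bool(rng.random() < 0.5)
            base = predict_risk(spec, make_derived(age, fem, **flags))
            for t in spec.terms:
                if t.feature in flags and t.coefficient > 0:
                    on = dict(flags)
                    on[t.feature] = True
                    if t.feature == "ihd_or_stroke" or t.feature == "ihd":
                        pass  # independent flags here, no linkage needed
                    risk_on = predict_risk(spec, make_derived(age, fem, **on))
                    if not flags[t.feature]:
                        assert risk_on >= base


class TestScoring:
    def test_published_score_ranges(self, score_tables):
        expected = {"scored": (0, 12), "modified_scored": (0, 10),
                    "kshirsagar": (0, 9), "kwon": (0, 10),
                    "thakkinstian": (0, 16)}
        assert {n: t.score_range for n, t in score_tables.items()} == expected

    def test_kearns_has_no_score_table(self, score_tables):
        assert "kearns" not in score_tables

    def test_empty_profile_scores_zero(self, score_tables):
        d = make_derived(45)
        assert all(score(t, d) == 0 for t in score_tables.values())

    def test_scored_worked_example(self, score_tables):
        d = make_derived(65, female=True, hypertension=True, ihd_or_stroke=True)
        assert score(score_tables["scored"], d) == 3 + 1 + 1 + 1

    def test_score_within_range_and_monotone(self, score_tables):
        rng = np.random.default_rng(2)
        for _ in range(200):
            name = rng.choice(list(score_tables))
            t = score_tables[name]
            flags = {f: bool(rng.random() < 0.4) for f in ALL_FLAGS}
            d = make_derived(float(rng.uniform(40, 80)),
                             bool(rng.random() < 0.5), **flags)
            s = score(t, d)
            assert t.score_range[0] <= s <= t.score_range[1]
            off_feature = rng.choice([f for f in ALL_FLAGS if not flags[f]])
            flags2 = dict(flags)
            flags2[off_feature] = True
            d2 = make_derived(d.age, d.female, **flags2)
            assert score(t, d2) >= s

    def test_score_ignores_out_of_model_predictors(self, score_tables):
        base = make_derived(65, female=True, hypertension=True)
        extra = make_derived(65, female=True, hypertension=True,
                             kidney_stones=True, pvd=True, proteinuria=True)
        t = score_tables["modified_scored"]  # uses none of the extras
        assert score(t, base) == score(t, extra)

    @pytest.mark.parametrize("s,thr,expected", [(6, 6, True), (5, 6, False),
                                                (12, 4, True)])
    def test_classify_inclusive(self, s, thr, expected, score_tables):
        assert classify(s, thr, score_tables["scored"]) is expected

    def test_classify_threshold_outside_range(self, score_tables):
        with pytest.raises(ValueError):
            classify(5, 13, score_tables["scored"])

    def test_thresholds_within_ranges(self, score_tables):
        for t in score_tables.values():
            lo, hi = t.score_range
            assert all(lo <= thr <= hi for thr in t.published_thresholds)


class TestConfigRoundTrip:
    def test_yaml_round_trip(self, registry, score_tables):
        doc = models_to_config(registry.values(), score_tables)
        doc2 = yaml.safe_load(yaml.safe_dump(doc))
        specs, tables = models_from_config(doc2)
        assert specs == registry
        for name, t in score_tables.items():
            assert dict(tables[name].points) == dict(t.points)
            assert tables[name].score_range == t.score_range
            assert tables[name].published_thresholds == t.published_thresholds

    def test_corrected_coefficients_swap_in(self, registry):
        doc = models_to_config(registry.values())
        doc["models"]["thakkinstian"]["intercept"] = -2.8
        specs, _ = models_from_config(doc)
        assert specs["thakkinstian"].intercept == -2.8
        assert specs["scored"] == registry["scored"]
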