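"""Probability calculus, risk-model plumbing and the stratum assumptions."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from obesim import (
    HazardRatioTable,
    LogisticRiskModel,
    RiskModelRegistry,
    annual_probability,
    apply_hazard_ratio,
    complication_probability,
    compound_probability,
    cv_event_probability,
    t2d_incidence,
    toy_registry,
)
from obesim.risk import (
    HazardRatioStratum,
    Population,
    Term,
    load_risk_model,
    toy_t2d_model,
    zero_registry,
)


class TestAnnualProbability:
    @pytest.mark.parametrize(
        "cum, k, expected",
        [
            (0.0, 10, 0.0),
            (1.0, 8, 1.0),
            (0.40, 10, 0.049800),  # 1 - 0.6**0.1, round-trips to 0.40
        ],
    )
    def test_values(self, cum, k, expected):
        assert annual_probability(cum, k) == pytest.approx(expected, abs=5e-7)

    def test_compounding_recovers_cumulative_risk(self):
        p = annual_probability(0.40, 10)
        # survive ten one-year cycles
        assert 1 - (1 - p) ** 10 == pytest.approx(0.40, abs=1e-12)

    @given(st.floats(0.0, 0.999999), st.integers(1, 40))
    @settings(max_examples=200, deadline=None)
    def test_round_trip_identity(self, cum, k):
        assert compound_probability(annual_probability(cum, k), k) == pytest.approx(
            cum, abs=1e-9
        )

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            annual_probability(1.2, 10)
        with pytest.raises(ValueError):
            annual_probability(0.5, 0)


class TestApplyHazardRatio:
    @pytest.mark.parametrize(
        "p, hr, expected",
        [(0.01, 1.0, 0.01), (0.0, 5.0, 0.0), (0.30, 2.0, 0.51)],
    )
    def test_values(self, p, hr, expected):
        assert apply_hazard_ratio(p, hr) == pytest.approx(expected, abs=1e-12)

    @given(
        st.floats(0.0, 1.0),
        st.floats(0.01, 50.0),
        st.floats(0.01, 50.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_monotone_in_hr(self, p, hr1, hr2):
        lo, hi = sorted((hr1, hr2))
        a, b = apply_hazard_ratio(p, lo), apply_hazard_ratio(p, hi)
        assert 0.0 <= a <= b <= 1.0

    def test_monotone_in_p(self):
        assert apply_hazard_ratio(0.02, 1.5) < apply_hazard_ratio(0.05, 1.5)


class TestT2DIncidence:
    def test_zero_risk_stub_gives_zero(self, rf, zero_risk_registry):
        assert t2d_incidence(rf, "NGT", zero_risk_registry["t2d_incidence"]) == 0.0

    def test_prediabetes_at_least_ngt_under_monotone_model(self, rf):
        model = toy_t2d_model()
        assert t2d_incidence(rf, "PREDIABETES", model) >= t2d_incidence(
            rf, "NGT", model
        )

    def test_already_diabetic_stratum_rejected(self, rf):
        with pytest.raises(ValueError, match="T2D"):
            t2d_incidence(rf, "T2D", toy_t2d_model())

    def test_toy_logistic_matches_independent_formula(self, rf):
        """Direct spreadsheet-style evaluation of the documented coefficients."""
        # prediabetes: marker forced to 6.0%
        lp = -5.0 + 0.16 * (rf.bmi - 22.5) + 2.2 * (6.0 - 5.4) + 0.015 * (rf.age - 50.0)
        ten_year = 1.0 / (1.0 + math.exp(-lp))
        expected = 1.0 - (1.0 - ten_year) ** 0.1
        got = t2d_incidence(rf, "PREDIABETES", toy_t2d_model())
        assert got == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_bmi_for_bmi_monotone_model(self, rf):
        import dataclasses

        model = toy_t2d_model()
        probs = [
            t2d_incidence(dataclasses.replace(rf, bmi=b), "NGT", model)
            for b in (22.5, 27.3, 32.1, 37.0, 42.3)
        ]
        assert probs == sorted(probs)


class TestCVEventProbability:
    def test_prediabetes_first_maps_to_ngt_model(self, rf, registry):
        assert cv_event_probability(rf, "PREDIABETES", "first", registry) == (
            cv_event_probability(rf, "NGT", "first", registry)
        )

    def test_prediabetes_recurrent_maps_to_t2d_model(self, rf, registry):
        assert cv_event_probability(rf, "PREDIABETES", "recurrent", registry) == (
            cv_event_probability(rf, "T2D", "recurrent", registry)
        )

    def test_zero_registry_gives_zero_pair(self, rf, zero_risk_registry):
        assert cv_event_probability(rf, "NGT", "first", zero_risk_registry) == (0.0, 0.0)

    def test_missing_slot_raises_with_slot_name(self, rf):
        reg = RiskModelRegistry({"t2d_incidence": toy_t2d_model()})
        with pytest.raises(KeyError, match="cv_first_ngt"):
            cv_event_probability(rf, "NGT", "first", reg)

    def test_split_partitions_composite_risk(self, rf, registry):
        acs, stroke = cv_event_probability(rf, "NGT", "first", registry, acs_share=0.25)
        assert acs == pytest.approx(stroke / 3.0)


def _hr_table():
    return HazardRatioTable(
        "t2d",
        (
            HazardRatioStratum(18.5, 25.0, 1.0),
            HazardRatioStratum(25.0, 30.0, 2.0),
            HazardRatioStratum(30.0, 45.0, 4.0),
        ),
    )


class TestComplicationProbability:
    def test_reference_stratum_returns_baseline(self, rf):
        assert complication_probability(rf, "knee_replacement", _hr_table(), 0.002) == (
            pytest.approx(0.002)
        )

    def test_hr_two_closed_form(self, rf):
        import dataclasses

        rf2 = dataclasses.replace(rf, bmi=27.0)
        got = complication_probability(rf2, "knee_replacement", _hr_table(), 0.001)
        assert got == pytest.approx(1 - 0.999**2, abs=1e-12)  # 0.001999

    def test_postmenopausal_cancer_zero_below_menopause_age(self, rf):
        import dataclasses

        young = dataclasses.replace(rf, age=40.0, menopause_age=51.0)
        assert complication_probability(young, "endometrial_pm", _hr_table(), 0.01) == 0.0

    def test_postmenopausal_cancer_scaled_by_female_share(self, rf):
        import dataclasses

        older = dataclasses.replace(rf, age=60.0)
        got = complication_probability(older, "breast_pm", _hr_table(), 0.01)
        assert got == pytest.approx(rf.sex_share_women * 0.01)

    def test_bmi_outside_strata_clamped_with_warning(self, rf, caplog):
        import dataclasses

        heavy = dataclasses.replace(rf, bmi=55.0)
        with caplog.at_level("WARNING"):
            got = complication_probability(heavy, "knee_replacement", _hr_table(), 0.001)
        assert "clamped" in caplog.text
        assert got == pytest.approx(1 - 0.999**4, abs=1e-12)


class TestHazardRatioTable:
    def test_requires_reference_stratum(self):
        with pytest.raises(ValueError, match="reference"):
            HazardRatioTable("x", (HazardRatioStratum(18.5, 25.0, 2.0),))

    def test_rejects_overlapping_strata(self):
        with pytest.raises(ValueError, match="overlap"):
            HazardRatioTable(
                "x",
                (
                    HazardRatioStratum(18.5, 26.0, 1.0),
                    HazardRatioStratum(25.0, 30.0, 2.0),
                ),
            )

    def test_half_open_boundaries(self):
        t = _hr_table()
        assert t.lookup(25.0) == 2.0
        assert t.lookup(24.999) == 1.0


class TestModelLoading:
    def test_json_round_trip(self, tmp_path, rf):
        spec = {
            "name": "custom",
            "kind": "logistic",
            "horizon_years": 10,
            "population": "ANY",
            "intercept": -5.0,
            "terms": [
                {"term": "bmi", "coefficient": 0.16, "ref": 22.5},
                {"term": "hba1c_pct", "coefficient": 2.2, "ref": 5.4},
                {"term": "age", "coefficient": 0.015, "ref": 50.0},
            ],
        }
        import json

        path = tmp_path / "model.json"
        path.write_text(json.dumps(spec))
        model = load_risk_model(path)
        assert model.evaluate(rf) == pytest.approx(toy_t2d_model().evaluate(rf))

    def test_baseline_survival_kind(self, tmp_path, rf):
        import json

        spec = {
            "name": "coxish",
            "kind": "baseline_survival",
            "horizon_years": 10,
            "population": "ANY",
            "baseline_survival": 0.95,
            "terms": [{"term": "bmi", "coefficient": 0.05, "ref": 25.0}],
        }
        path = tmp_path / "model.json"
        path.write_text(json.dumps(spec))
        model = load_risk_model(path)
        lp = 0.05 * (rf.bmi - 25.0)
        assert model.evaluate(rf) == pytest.approx(1 - 0.95 ** math.exp(lp))

    def test_probabilities_in_unit_interval_over_random_vectors(self):
        from obesim import RiskFactorVector

        reg = toy_registry()

        @given(
            st.floats(25, 85),
            st.floats(15, 60),
            st.floats(90, 200),
            st.floats(0, 1),
        )
        @settings(max_examples=100, deadline=None)
        def check(age, bmi, sbp, women):
            v = RiskFactorVector(age=age, sex_share_women=women, bmi=bmi, sbp=sbp)
            p = t2d_incidence(v, "PREDIABETES", reg["t2d_incidence"])
            acs, stroke = cv_event_probability(v, "T2D", "recurrent", reg)
            assert 0.0 <= p <= 1.0
            assert 0.0 <= acs <= 1.0 and 0.0 <= stroke <= 1.0

        check()
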