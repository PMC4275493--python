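"""Rules engine: risk taxonomy, indications, targets, and invariants."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvdrules.chart import RiskCategory
from cvdrules.engine import (
    CALCULATED_VARIABLE_NAMES,
    NOT_EVALUABLE,
    RiskAssessment,
    antiplatelet_indication,
    assess_patient,
    assess_risk,
    bp_med_indication,
    calculated_variables,
    clinically_high_risk,
    diabetes_status,
    established_cvd,
    referral_and_lifestyle,
    statin_indication,
    treatment_targets,
    underestimation_flags,
)

from conftest import make_record


def banded_assessment(category: str, pathway="high_info") -> RiskAssessment:
    """Assessment stub for gate tests that step through the risk bands."""
    chart_cat = (
        RiskCategory[category] if category in RiskCategory.__members__ else RiskCategory.LT10
    )
    return RiskAssessment(
        imputed_age=55.0,
        pathway=pathway,
        chart_category=chart_cat,
        adjusted_category=category,
        chr_reasons=frozenset(),
        underestimation_flags=frozenset(),
    )


class TestEstablishedCvd:
    @pytest.mark.parametrize(
        "overrides,expected",
        [
            (dict(hx_stroke=True), True),
            (dict(hx_pvd=True), True),
            (dict(hx_angina_or_mi=True), True),
            (dict(), False),
        ],
    )
    def test_history_flags(self, overrides, expected):
        assert established_cvd(make_record(**overrides)) is expected


class TestClinicallyHighRisk:
    def test_sbp_threshold_inclusive(self):
        flag, reasons = clinically_high_risk(make_record(sbp=160, dbp=80))
        assert flag and reasons == {"SBP>=160"}

    def test_all_strict_sides_negative(self):
        # every criterion one unit below its cut (ratio exactly 8 is not >8)
        rec = make_record(sbp=159, dbp=99, tc=319, ldl=239, hdl=39.875)
        assert rec.tc / rec.hdl == 8.0
        flag, reasons = clinically_high_risk(rec)
        assert not flag and reasons == frozenset()

    def test_single_criterion_with_missing_hdl(self):
        flag, reasons = clinically_high_risk(make_record(tc=320, hdl=None))
        assert flag and reasons == {"TC>=320"}

    def test_ratio_strictly_above_8(self):
        flag, reasons = clinically_high_risk(make_record(tc=324, hdl=40))
        assert "TC/HDL>8" in reasons

    def test_dbp_threshold(self):
        assert clinically_high_risk(make_record(dbp=100))[0]
        assert not clinically_high_risk(make_record(dbp=99))[0]


class TestUnderestimationFlags:
    @pytest.mark.parametrize(
        "overrides,flag,present",
        [
            (dict(heart_rate=101), "raised_heart_rate", True),
            (dict(heart_rate=100), "raised_heart_rate", False),
            (dict(sex="male", hdl=39), "low_hdl", True),
            (dict(sex="male", hdl=40), "low_hdl", False),
            (dict(sex="female", hdl=49), "low_hdl", True),
            (dict(sex="female", hdl=50), "low_hdl", False),
            (dict(tg=181), "raised_tg", True),
            (dict(tg=180), "raised_tg", False),
            (dict(on_bp_lowering=True), "on_bp_med", True),
            (dict(fam_hx_premature_chd_or_stroke=True), "family_history", True),
            (dict(fasting_glucose=110), "fasting_dysglycemia", True),
            (dict(fasting_glucose=125), "fasting_dysglycemia", True),
            (dict(fasting_glucose=109), "fasting_dysglycemia", False),
            (dict(fasting_glucose=126), "fasting_dysglycemia", False),
            (dict(weight=71), "obesity", True),  # BMI 27.7 at 160 cm
            (dict(waist=80), "obesity", True),  # female central cut
            (dict(sex="male", waist=89), "obesity", False),
            (dict(sex="male", waist=90), "obesity", True),
        ],
    )
    def test_flag_boundaries(self, overrides, flag, present):
        flags = underestimation_flags(make_record(**overrides))
        assert (flag in flags) is present

    def test_absent_inputs_never_flag(self):
        flags = underestimation_flags(
            make_record(tg=None, hdl=None, fasting_glucose=None, waist=None)
        )
        assert not {"raised_tg", "low_hdl", "fasting_dysglycemia"} & flags


class TestDiabetesStatus:
    @pytest.mark.parametrize(
        "overrides,expected",
        [
            (dict(fasting_glucose=126), True),
            (dict(fasting_glucose=125), False),
            (dict(glucose_is_fasting=False, fasting_glucose=None, random_glucose=199), False),
            (dict(glucose_is_fasting=False, fasting_glucose=None, random_glucose=200), True),
            (dict(hx_diabetes=True, fasting_glucose=None, glucose_is_fasting=None), True),
            (dict(), False),
        ],
    )
    def test_thresholds(self, overrides, expected):
        assert diabetes_status(make_record(**overrides)) is expected


class TestAssessRisk:
    def test_cvd_and_chr(self, chart):
        a = assess_risk(make_record(hx_stroke=True, sbp=170), chart)
        assert a.adjusted_category == "CVD_AND_CHR"

    def test_cvd_only(self, chart):
        a = assess_risk(make_record(hx_pvd=True), chart)
        assert a.adjusted_category == "CVD"

    def test_chr_only(self, chart):
        a = assess_risk(make_record(sbp=165), chart)
        assert a.adjusted_category == "CHR"

    def test_no_override_uses_chart(self, chart):
        a = assess_risk(make_record(), chart)
        assert a.adjusted_category == a.chart_category.name

    def test_low_info_pathway_without_cholesterol(self, chart):
        a = assess_risk(make_record(tc=None, ldl=None, hdl=None, tg=None), chart)
        assert a.pathway == "low_info"

    def test_elevated_glucose_feeds_chart_diabetes(self, chart):
        base = assess_risk(make_record(age=75, sbp=150), chart)
        dm = assess_risk(make_record(age=75, sbp=150, fasting_glucose=130), chart)
        assert dm.chart_category >= base.chart_category


class TestBpMedIndication:
    def test_moderate_bp_with_risk_gt_20(self):
        rec = make_record(sbp=145, dbp=88)
        flag, reasons = bp_med_indication(rec, banded_assessment("R20_30"))
        assert flag and "bp_ge_140_90_and_risk_gt_20" in reasons

    def test_mild_bp_with_risk_gt_30(self):
        rec = make_record(sbp=132, dbp=78)
        flag, reasons = bp_med_indication(rec, banded_assessment("R30_40"))
        assert flag and "bp_ge_130_80_and_risk_gt_30" in reasons

    def test_no_criterion_met(self):
        rec = make_record(sbp=128, dbp=78)
        flag, _ = bp_med_indication(rec, banded_assessment("LT10"))
        assert not flag

    def test_moderate_bp_without_risk_not_indicated(self):
        rec = make_record(sbp=145, dbp=88)
        flag, _ = bp_med_indication(rec, banded_assessment("R10_20"))
        assert not flag

    def test_extreme_bp_alone_indicates(self):
        rec = make_record(sbp=160)
        flag, reasons = bp_med_indication(rec, banded_assessment("LT10"))
        assert flag and "bp_ge_160_100" in reasons


class TestStatinIndication:
    def test_age_risk_lipid_gate(self):
        rec = make_record(age=45, tc=200)
        flag, reasons = statin_indication(rec, banded_assessment("R20_30"))
        assert flag and "age_ge_40_risk_gt_20_raised_lipids" in reasons

    def test_age_gate_blocks_under_40(self):
        rec = make_record(age=39, tc=250)
        flag, _ = statin_indication(rec, banded_assessment("R20_30"))
        assert not flag

    def test_diabetes_history_alone(self):
        rec = make_record(hx_diabetes=True)
        flag, reasons = statin_indication(rec, banded_assessment("LT10"))
        assert flag and "diabetes" in reasons

    def test_ldl_branch_of_lipid_gate(self):
        rec = make_record(age=62, ldl=120, tc=150)
        flag, _ = statin_indication(rec, banded_assessment("R20_30"))
        assert flag


class TestAntiplateletIndication:
    def test_risk_gate_strictly_above_30(self):
        rec = make_record(sbp=118, dbp=76)
        assert antiplatelet_indication(rec, banded_assessment("R30_40"))[0]
        assert not antiplatelet_indication(rec, banded_assessment("R20_30"))[0]

    def test_cvd_history(self):
        rec = make_record(hx_angina_or_mi=True)
        flag, reasons = antiplatelet_indication(rec, banded_assessment("CVD"))
        assert flag and "atherosclerotic_cvd" in reasons


class TestTreatmentTargets:
    def test_cvd_tier(self):
        bp, lipid = treatment_targets(make_record(hx_stroke=True), banded_assessment("CVD"))
        assert bp == (130, 80) and lipid == (160, 80, 45)

    def test_default_tier(self):
        bp, lipid = treatment_targets(make_record(), banded_assessment("LT10"))
        assert bp == (140, 90) and lipid == (200, 120, 40)

    def test_diabetes_tier(self):
        bp, lipid = treatment_targets(make_record(hx_diabetes=True), banded_assessment("LT10"))
        assert bp == (130, 80) and lipid == (180, 100, 45)


class TestReferralAndLifestyle:
    def test_smoker_gets_cessation_advice(self, chart):
        a = assess_patient(make_record(current_smoker=True), chart)
        assert "smoking_cessation" in a.plan.lifestyle_advice

    def test_chr_triggers_referral(self, chart):
        a = assess_patient(make_record(sbp=165), chart)
        assert a.assessment.adjusted_category == "CHR"
        assert a.plan.referral_indicated

    def test_low_risk_no_referral(self, chart):
        a = assess_patient(make_record(), chart)
        assert not a.plan.referral_indicated

    def test_new_diabetes_referred_for_testing(self, chart):
        rec = make_record(age=40, fasting_glucose=130)
        a = assess_patient(rec, chart)
        assert a.plan.referral_indicated


class TestCalculatedVariables:
    def test_exactly_42_entries(self, chart, record):
        values = calculated_variables(record, chart)
        assert len(values) == 42
        assert tuple(values) == CALCULATED_VARIABLE_NAMES

    def test_complete_record_fully_evaluable(self, chart):
        # every optional measurement present, including both glucose readings
        values = calculated_variables(make_record(random_glucose=95), chart)
        assert NOT_EVALUABLE not in values.values()

    def test_missing_cholesterol_marks_derived_entries(self, chart):
        rec = make_record(tc=None, ldl=None, hdl=None, tg=None)
        values = calculated_variables(rec, chart)
        assert values["info_pathway"] == "low_info"
        for name in ("tc_band", "tc_mmol", "tc_hdl_ratio", "chr_tc", "chr_ldl",
                     "chr_ratio", "under_tg", "under_hdl"):
            assert values[name] == NOT_EVALUABLE, name

    def test_no_tc_reason_when_tc_missing(self, chart):
        rec = make_record(tc=None, ldl=None, hdl=None, tg=None, sbp=165)
        a = assess_patient(rec, chart)
        assert a.assessment.chr_reasons == {"SBP>=160"}


RANK = {"LT10": 0, "R10_20": 1, "R20_30": 2, "R30_40": 3, "GT40": 4,
        "CHR": 5, "CVD": 5, "CVD_AND_CHR": 6}


class TestEngineInvariants:
    @given(
        sbp_lo=st.integers(min_value=90, max_value=250),
        delta=st.integers(min_value=1, max_value=49),
        age=st.integers(min_value=18, max_value=95),
        smoker=st.booleans(),
        diabetic=st.booleans(),
    )
    @settings(deadline=None, max_examples=150)
    def test_sbp_monotone(self, chart, sbp_lo, delta, age, smoker, diabetic):
        """Raising SBP never lowers the category nor revokes an indication."""
        low = make_record(sbp=sbp_lo, dbp=70, age=age, current_smoker=smoker,
                          hx_diabetes=diabetic)
        high = low.replace(sbp=float(sbp_lo + delta))
        a_lo = assess_patient(low, chart)
        a_hi = assess_patient(high, chart)
        assert RANK[a_hi.assessment.adjusted_category] >= RANK[a_lo.assessment.adjusted_category]
        for attr in ("bp_med_indicated", "statin_indicated", "antiplatelet_indicated",
                     "referral_indicated"):
            assert not (getattr(a_lo.plan, attr) and not getattr(a_hi.plan, attr)), attr

    @pytest.mark.parametrize(
        "flag", ["hx_angina_or_mi", "hx_stroke", "hx_pvd", "hx_diabetes"]
    )
    def test_positive_history_never_loosens_care(self, chart, flag):
        from cvdrules.cohort import boundary_suite

        for rec in boundary_suite():
            base = assess_patient(rec, chart)
            flagged = assess_patient(rec.replace(**{flag: True}), chart)
            for attr in ("bp_med_indicated", "statin_indicated", "antiplatelet_indicated",
                         "referral_indicated"):
                assert not (getattr(base.plan, attr) and not getattr(flagged.plan, attr))
            assert flagged.plan.bp_target[0] <= base.plan.bp_target[0]
            assert flagged.plan.lipid_targets[0] <= base.plan.lipid_targets[0]

    def test_cvd_and_diabetes_always_tight_targets(self, chart):
        from cvdrules.cohort import boundary_suite

        for rec in boundary_suite():
            for flag, tier in (("hx_stroke", (160, 80, 45)), ("hx_diabetes", None)):
                a = assess_patient(rec.replace(**{flag: True}), chart)
                assert a.plan.bp_target == (130, 80)
                if tier is not None:
                    assert a.plan.lipid_targets == tier

    def test_determinism(self, chart, record):
        first = assess_patient(record, chart)
        second = assess_patient(record, chart)
        assert first.calculated == second.calculated
        assert first.plan == second.plan
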