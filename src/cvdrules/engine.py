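"""Guideline rules engine: risk assessment and management plan for one patient.

Implements the screening algorithm as plain, auditable predicate
functions over a :class:`~cvdrules.records.PatientRecord` and a
:class:`~cvdrules.chart.RiskChartSet`:

* chart risk lookup with age imputation and automatic high/low
  information pathway choice;
* the *adjusted* risk taxonomy — established CVD and single extreme
  risk factors (clinically high risk, CHR) override the chart band;
* risk-underestimation flags;
* medication indications (BP lowering, statin, antiplatelet),
  BP and lipid treatment targets, referral and lifestyle advice;
* the canonical 42-entry calculated-variable vector used by the
  dual-implementation validation harness.

Compound blood-pressure thresholds written "BP >=160/100 mm Hg" are
read disjunctively (SBP >=160 OR DBP >=100).  Printed operators are
followed literally: ``>=`` criteria are inclusive, ``>`` criteria
strict (TC/HDL ratio > 8, heart rate > 100, triglycerides > 180).
"Risk > 20%" means the adjusted category is at or above the 20-30%
band; "> 30%" at or above the 30-40% band; CHR and CVD categories
satisfy both gates (they are high risk throughout).  A rule whose
optional input is absent is false — missingness never triggers care.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .chart import RiskCategory, RiskChartSet, band_label, impute_chart_age, lookup_risk
from .records import PatientRecord

__all__ = [
    "NOT_EVALUABLE",
    "RuleThresholds",
    "RiskAssessment",
    "ManagementPlan",
    "AssessedPatient",
    "ADJUSTED_CATEGORIES",
    "CALCULATED_VARIABLE_NAMES",
    "established_cvd",
    "clinically_high_risk",
    "underestimation_flags",
    "diabetes_status",
    "assess_risk",
    "bp_med_indication",
    "statin_indication",
    "antiplatelet_indication",
    "treatment_targets",
    "referral_and_lifestyle",
    "calculated_variables",
    "assess_patient",
]

#: Marker for a calculated variable whose inputs were not measured.
NOT_EVALUABLE = "NE"

#: Adjusted risk taxonomy: the five chart bands plus the override categories.
ADJUSTED_CATEGORIES = ("LT10", "R10_20", "R20_30", "R30_40", "GT40", "CHR", "CVD", "CVD_AND_CHR")

_HIGH_RISK_OVERRIDES = frozenset({"CHR", "CVD", "CVD_AND_CHR"})
_BAND_ORDER = {c.name: int(c) for c in RiskCategory}


def risk_exceeds(adjusted_category: str, band: RiskCategory) -> bool:
    """True when the adjusted category satisfies a "risk > X%" gate.

    ``band`` is the lowest chart band that satisfies the gate
    (R20_30 for ">20%", R30_40 for ">30%").  Override categories
    (CHR/CVD/CVD_AND_CHR) always satisfy the gate.
    """
    if adjusted_category in _HIGH_RISK_OVERRIDES:
        return True
    return _BAND_ORDER[adjusted_category] >= int(band)


@dataclass(frozen=True)
class RuleThresholds:
    """Normative rule constants; a test hook for fault-injection studies.

    Defaults are the screening algorithm's published cut-points and
    must not be changed in production use.
    """

    chr_sbp: float = 160.0  # mm Hg, inclusive
    chr_dbp: float = 100.0  # mm Hg, inclusive
    chr_tc: float = 320.0  # mg/dL, inclusive
    chr_ldl: float = 240.0  # mg/dL, inclusive
    chr_ratio: float = 8.0  # TC/HDL, strict >
    fg_diabetes: float = 126.0  # mg/dL, inclusive
    rg_diabetes: float = 200.0  # mg/dL, inclusive
    fg_dysglycemia_lo: float = 110.0  # mg/dL, inclusive
    fg_dysglycemia_hi: float = 125.0  # mg/dL, inclusive
    tg_high: float = 180.0  # mg/dL, strict >
    hdl_low_male: float = 40.0  # mg/dL, strict <
    hdl_low_female: float = 50.0  # mg/dL, strict <
    hr_high: float = 100.0  # beats/min, strict >
    bmi_obese: float = 27.5  # kg/m^2, inclusive (Asian cut-point)
    waist_male: float = 90.0  # cm, inclusive
    waist_female: float = 80.0  # cm, inclusive
    bp_mod_sbp: float = 140.0  # mm Hg, with risk >20%
    bp_mod_dbp: float = 90.0
    bp_mild_sbp: float = 130.0  # mm Hg, with risk >30%
    bp_mild_dbp: float = 80.0
    statin_age: float = 40.0  # years, inclusive
    statin_tc: float = 200.0  # mg/dL, inclusive
    statin_ldl: float = 120.0  # mg/dL, inclusive


DEFAULT_THRESHOLDS = RuleThresholds()


@dataclass(frozen=True)
class RiskAssessment:
    imputed_age: float
    pathway: str  # "high_info" | "low_info"
    chart_category: RiskCategory
    adjusted_category: str  # one of ADJUSTED_CATEGORIES
    chr_reasons: frozenset
    underestimation_flags: frozenset


@dataclass(frozen=True)
class ManagementPlan:
    bp_med_indicated: bool
    bp_med_reasons: tuple
    statin_indicated: bool
    statin_reasons: tuple
    antiplatelet_indicated: bool
    antiplatelet_reasons: tuple
    bp_target: tuple  # (systolic, diastolic) mm Hg
    lipid_targets: tuple  # (tc <, ldl <, hdl >) mg/dL
    referral_indicated: bool
    lifestyle_advice: frozenset


@dataclass(frozen=True)
class AssessedPatient:
    """Full engine output for one record."""

    record: PatientRecord
    assessment: RiskAssessment
    plan: ManagementPlan
    calculated: dict = field(compare=False)


def established_cvd(record: PatientRecord) -> bool:
    """Prior angina/MI, stroke, or peripheral vascular disease."""
    return record.hx_angina_or_mi or record.hx_stroke or record.hx_pvd


def _tc_hdl_ratio(record: PatientRecord) -> Optional[float]:
    if record.tc is None or record.hdl is None or record.hdl == 0:
        return None
    return record.tc / record.hdl


def clinically_high_risk(
    record: PatientRecord, thresholds: RuleThresholds = DEFAULT_THRESHOLDS
) -> tuple[bool, frozenset]:
    """Single extreme risk factors that classify a patient high risk.

    Evaluated regardless of CVD status; the flag only produces the CHR
    *category* when established CVD is absent.  Reason codes:
    SBP>=160, DBP>=100, TC>=320, LDL>=240, TC/HDL>8.
    """
    t = thresholds
    reasons = set()
    if record.sbp >= t.chr_sbp:
        reasons.add("SBP>=160")
    if record.dbp >= t.chr_dbp:
        reasons.add("DBP>=100")
    if record.tc is not None and record.tc >= t.chr_tc:
        reasons.add("TC>=320")
    if record.ldl is not None and record.ldl >= t.chr_ldl:
        reasons.add("LDL>=240")
    ratio = _tc_hdl_ratio(record)
    if ratio is not None and ratio > t.chr_ratio:
        reasons.add("TC/HDL>8")
    return bool(reasons), frozenset(reasons)


def _obesity(record: PatientRecord, t: RuleThresholds) -> tuple[bool, Optional[bool]]:
    """(overall obesity flag, central obesity flag or None if waist absent)."""
    general = record.bmi >= t.bmi_obese
    central: Optional[bool] = None
    if record.waist is not None:
        cut = t.waist_male if record.sex == "male" else t.waist_female
        central = record.waist >= cut
    return general or bool(central), central


def underestimation_flags(
    record: PatientRecord, thresholds: RuleThresholds = DEFAULT_THRESHOLDS
) -> frozenset:
    """Conditions under which the chart band understates true risk.

    Each flag is evaluated only when its inputs were measured.
    """
    t = thresholds
    flags = set()
    if record.on_bp_lowering:
        flags.add("on_bp_med")
    obese, _central = _obesity(record, t)
    if obese:
        flags.add("obesity")
    if record.fam_hx_premature_chd_or_stroke:
        flags.add("family_history")
    if record.tg is not None and record.tg > t.tg_high:
        flags.add("raised_tg")
    if record.hdl is not None:
        cut = t.hdl_low_male if record.sex == "male" else t.hdl_low_female
        if record.hdl < cut:
            flags.add("low_hdl")
    if record.fasting_glucose is not None and (
        t.fg_dysglycemia_lo <= record.fasting_glucose <= t.fg_dysglycemia_hi
    ):
        flags.add("fasting_dysglycemia")
    if record.heart_rate > t.hr_high:
        flags.add("raised_heart_rate")
    return frozenset(flags)


def diabetes_status(
    record: PatientRecord, thresholds: RuleThresholds = DEFAULT_THRESHOLDS
) -> bool:
    """Known diabetes, fasting glucose >=126 mg/dL, or random glucose >=200 mg/dL."""
    t = thresholds
    if record.hx_diabetes:
        return True
    if record.fasting_glucose is not None and record.fasting_glucose >= t.fg_diabetes:
        return True
    if record.random_glucose is not None and record.random_glucose >= t.rg_diabetes:
        return True
    return False


def assess_risk(
    record: PatientRecord,
    chart_set: RiskChartSet,
    thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
) -> RiskAssessment:
    """Chart band plus the adjusted category and underestimation flags."""
    dm = diabetes_status(record, thresholds)
    chart_cat, pathway = lookup_risk(
        chart_set, record.sex, dm, record.current_smoker,
        record.age, record.sbp, tc=record.tc, tc_units="mg/dL",
    )
    cvd = established_cvd(record)
    chr_flag, chr_reasons = clinically_high_risk(record, thresholds)
    if cvd and chr_flag:
        adjusted = "CVD_AND_CHR"
    elif cvd:
        adjusted = "CVD"
    elif chr_flag:
        adjusted = "CHR"
    else:
        adjusted = chart_cat.name
    return RiskAssessment(
        imputed_age=impute_chart_age(record.age),
        pathway=pathway,
        chart_category=chart_cat,
        adjusted_category=adjusted,
        chr_reasons=chr_reasons,
        underestimation_flags=underestimation_flags(record, thresholds),
    )


def _lipid_extreme(record: PatientRecord, t: RuleThresholds) -> bool:
    """TC >=320 mg/dL or LDL >=240 mg/dL or TC/HDL > 8 (absent labs: false)."""
    if record.tc is not None and record.tc >= t.chr_tc:
        return True
    if record.ldl is not None and record.ldl >= t.chr_ldl:
        return True
    ratio = _tc_hdl_ratio(record)
    return ratio is not None and ratio > t.chr_ratio


def bp_med_indication(
    record: PatientRecord,
    assessment: RiskAssessment,
    thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
) -> tuple[bool, tuple]:
    t = thresholds
    reasons = []
    if established_cvd(record):
        reasons.append("established_cvd")
    if record.sbp >= t.chr_sbp or record.dbp >= t.chr_dbp:
        reasons.append("bp_ge_160_100")
    if (record.sbp >= t.bp_mod_sbp or record.dbp >= t.bp_mod_dbp) and risk_exceeds(
        assessment.adjusted_category, RiskCategory.R20_30
    ):
        reasons.append("bp_ge_140_90_and_risk_gt_20")
    if (record.sbp >= t.bp_mild_sbp or record.dbp >= t.bp_mild_dbp) and risk_exceeds(
        assessment.adjusted_category, RiskCategory.R30_40
    ):
        reasons.append("bp_ge_130_80_and_risk_gt_30")
    if _lipid_extreme(record, t):
        reasons.append("extreme_lipids")
    return bool(reasons), tuple(reasons)


def statin_indication(
    record: PatientRecord,
    assessment: RiskAssessment,
    thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
) -> tuple[bool, tuple]:
    t = thresholds
    reasons = []
    if established_cvd(record):
        reasons.append("established_cvd")
    if diabetes_status(record, t):
        reasons.append("diabetes")
    if _lipid_extreme(record, t):
        reasons.append("extreme_lipids")
    if record.sbp >= t.chr_sbp or record.dbp >= t.chr_dbp:
        reasons.append("bp_ge_160_100")
    if risk_exceeds(assessment.adjusted_category, RiskCategory.R30_40):
        reasons.append("risk_gt_30")
    if (
        record.age >= t.statin_age
        and risk_exceeds(assessment.adjusted_category, RiskCategory.R20_30)
        and (
            (record.tc is not None and record.tc >= t.statin_tc)
            or (record.ldl is not None and record.ldl >= t.statin_ldl)
        )
    ):
        reasons.append("age_ge_40_risk_gt_20_raised_lipids")
    return bool(reasons), tuple(reasons)


def antiplatelet_indication(
    record: PatientRecord,
    assessment: RiskAssessment,
    thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
) -> tuple[bool, tuple]:
    t = thresholds
    reasons = []
    if established_cvd(record):  # atherosclerotic CVD: angina/MI, stroke, PVD
        reasons.append("atherosclerotic_cvd")
    if _lipid_extreme(record, t):
        reasons.append("extreme_lipids")
    if record.sbp >= t.chr_sbp or record.dbp >= t.chr_dbp:
        reasons.append("bp_ge_160_100")
    if risk_exceeds(assessment.adjusted_category, RiskCategory.R30_40):
        reasons.append("risk_gt_30")
    return bool(reasons), tuple(reasons)


def treatment_targets(
    record: PatientRecord,
    assessment: RiskAssessment,
    thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
) -> tuple[tuple, tuple]:
    """(BP target, lipid targets) for this patient.

    BP target <130/80 mm Hg for established CVD, diabetes, or extreme
    lipids; <140/90 for all others.  Lipid tiers (TC <, LDL <, HDL >):
    CVD (160, 80, 45); diabetes (180, 100, 45); others (200, 120, 40).
    """
    t = thresholds
    tight = established_cvd(record) or diabetes_status(record, t) or _lipid_extreme(record, t)
    bp_target = (130, 80) if tight else (140, 90)
    if established_cvd(record):
        lipid = (160, 80, 45)
    elif diabetes_status(record, t):
        lipid = (180, 100, 45)
    else:
        lipid = (200, 120, 40)
    return bp_target, lipid


def referral_and_lifestyle(
    record: PatientRecord,
    assessment: RiskAssessment,
    plan_flags: tuple[bool, bool, bool],
    thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
) -> tuple[bool, frozenset]:
    """Referral decision and lifestyle advice set.

    Referral: adjusted category at/above the 20-30% band or any
    override category, any medication indicated, or newly detected
    diabetes (elevated glucose without a prior diagnosis).  Advice:
    smoking cessation for current smokers; diet and physical activity
    whenever obesity or any elevated risk factor is present.
    """
    bp_ind, statin_ind, apl_ind = plan_flags
    referral = (
        risk_exceeds(assessment.adjusted_category, RiskCategory.R20_30)
        or bp_ind
        or statin_ind
        or apl_ind
        or (diabetes_status(record, thresholds) and not record.hx_diabetes)
    )
    advice = set()
    if record.current_smoker:
        advice.add("smoking_cessation")
    obese, _ = _obesity(record, thresholds)
    elevated = (
        obese
        or bool(assessment.underestimation_flags)
        or bool(assessment.chr_reasons)
        or established_cvd(record)
        or diabetes_status(record, thresholds)
        or record.current_smoker
        or risk_exceeds(assessment.adjusted_category, RiskCategory.R10_20)
    )
    if elevated:
        advice.add("diet")
        advice.add("physical_activity")
    return referral, frozenset(advice)


#: Normative 42-entry calculated-variable registry (output order is fixed).
CALCULATED_VARIABLE_NAMES: tuple[str, ...] = (
    "imputed_chart_age", "age_band", "sbp_band", "tc_band", "tc_mmol",
    "tc_hdl_ratio", "bmi", "obesity_flag", "central_obesity_flag",
    "established_cvd", "atherosclerotic_cvd", "diabetes_status",
    "elevated_fasting_glucose", "elevated_random_glucose", "elevated_glucose_any",
    "chr_sbp", "chr_dbp", "chr_tc", "chr_ldl", "chr_ratio", "clinically_high_risk",
    "under_bp_med", "under_obesity", "under_fam_hx", "under_tg", "under_hdl",
    "under_dysglycemia", "under_heart_rate", "underestimation_any",
    "info_pathway", "chart_risk_category", "adjusted_risk_category",
    "bp_med_indicated", "statin_indicated", "antiplatelet_indicated",
    "bp_target_systolic", "bp_target_diastolic", "tc_target", "ldl_target",
    "hdl_target", "referral_indicated", "lifestyle_advice_any",
)


def calculated_variables(
    record: PatientRecord,
    chart_set: RiskChartSet,
    thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
) -> dict:
    """The canonical 42-entry derived-variable vector for one record.

    Entries whose inputs were not measured carry the explicit
    :data:`NOT_EVALUABLE` marker, never a silent default.
    """
    from .chart import MG_PER_DL_PER_MMOL

    t = thresholds
    assessment = assess_risk(record, chart_set, t)
    bp_ind, _ = bp_med_indication(record, assessment, t)
    st_ind, _ = statin_indication(record, assessment, t)
    ap_ind, _ = antiplatelet_indication(record, assessment, t)
    bp_target, lipid = treatment_targets(record, assessment, t)
    referral, advice = referral_and_lifestyle(record, assessment, (bp_ind, st_ind, ap_ind), t)

    age_band = chart_set.axis("age_band").band_of(assessment.imputed_age)
    sbp_band = chart_set.axis("sbp_band").band_of(record.sbp)
    if record.tc is None:
        tc_band_val = NOT_EVALUABLE
        tc_mmol = NOT_EVALUABLE
    else:
        tc_mmol = record.tc / MG_PER_DL_PER_MMOL
        tc_band_val = band_label(chart_set.axis("tc_band").band_of(tc_mmol))
    ratio = _tc_hdl_ratio(record)
    obese, central = _obesity(record, t)
    ue = assessment.underestimation_flags
    efg = (
        NOT_EVALUABLE if record.fasting_glucose is None
        else record.fasting_glucose >= t.fg_diabetes
    )
    erg = (
        NOT_EVALUABLE if record.random_glucose is None
        else record.random_glucose >= t.rg_diabetes
    )
    values = {
        "imputed_chart_age": assessment.imputed_age,
        "age_band": band_label(age_band),
        "sbp_band": band_label(sbp_band),
        "tc_band": tc_band_val,
        "tc_mmol": tc_mmol,
        "tc_hdl_ratio": NOT_EVALUABLE if ratio is None else ratio,
        "bmi": record.bmi,
        "obesity_flag": obese,
        "central_obesity_flag": NOT_EVALUABLE if central is None else central,
        "established_cvd": established_cvd(record),
        "atherosclerotic_cvd": established_cvd(record),
        "diabetes_status": diabetes_status(record, t),
        "elevated_fasting_glucose": efg,
        "elevated_random_glucose": erg,
        "elevated_glucose_any": (efg is True) or (erg is True),
        "chr_sbp": record.sbp >= t.chr_sbp,
        "chr_dbp": record.dbp >= t.chr_dbp,
        "chr_tc": NOT_EVALUABLE if record.tc is None else record.tc >= t.chr_tc,
        "chr_ldl": NOT_EVALUABLE if record.ldl is None else record.ldl >= t.chr_ldl,
        "chr_ratio": NOT_EVALUABLE if ratio is None else ratio > t.chr_ratio,
        "clinically_high_risk": bool(assessment.chr_reasons),
        "under_bp_med": "on_bp_med" in ue,
        "under_obesity": "obesity" in ue,
        "under_fam_hx": "family_history" in ue,
        "under_tg": NOT_EVALUABLE if record.tg is None else "raised_tg" in ue,
        "under_hdl": NOT_EVALUABLE if record.hdl is None else "low_hdl" in ue,
        "under_dysglycemia": (
            NOT_EVALUABLE if record.fasting_glucose is None else "fasting_dysglycemia" in ue
        ),
        "under_heart_rate": "raised_heart_rate" in ue,
        "underestimation_any": bool(ue),
        "info_pathway": assessment.pathway,
        "chart_risk_category": assessment.chart_category.name,
        "adjusted_risk_category": assessment.adjusted_category,
        "bp_med_indicated": bp_ind,
        "statin_indicated": st_ind,
        "antiplatelet_indicated": ap_ind,
        "bp_target_systolic": bp_target[0],
        "bp_target_diastolic": bp_target[1],
        "tc_target": lipid[0],
        "ldl_target": lipid[1],
        "hdl_target": lipid[2],
        "referral_indicated": referral,
        "lifestyle_advice_any": bool(advice),
    }
    assert tuple(values) == CALCULATED_VARIABLE_NAMES
    return values


def assess_patient(
    record: PatientRecord,
    chart_set: RiskChartSet,
    thresholds: RuleThresholds = DEFAULT_THRESHOLDS,
) -> AssessedPatient:
    """Run the full engine on one record."""
    t = thresholds
    assessment = assess_risk(record, chart_set, t)
    bp_ind, bp_reasons = bp_med_indication(record, assessment, t)
    st_ind, st_reasons = statin_indication(record, assessment, t)
    ap_ind, ap_reasons = antiplatelet_indication(record, assessment, t)
    bp_target, lipid = treatment_targets(record, assessment, t)
    referral, advice = referral_and_lifestyle(record, assessment, (bp_ind, st_ind, ap_ind), t)
    plan = ManagementPlan(
        bp_med_indicated=bp_ind,
        bp_med_reasons=bp_reasons,
        statin_indicated=st_ind,
        statin_reasons=st_reasons,
        antiplatelet_indicated=ap_ind,
        antiplatelet_reasons=ap_reasons,
        bp_target=bp_target,
        lipid_targets=lipid,
        referral_indicated=referral,
        lifestyle_advice=advice,
    )
    return AssessedPatient(
        record=record,
        assessment=assessment,
        plan=plan,
        calculated=calculated_variables(record, chart_set, t),
    )
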