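"""Dual-implementation validation harness.

The screening algorithm is validated the way clinical decision support
tools are in practice: a second implementation of the same plain
language rules, written independently as one flat decision table, is
run over the same records, and per-variable agreement between the two
programs is reported.  Agreement of 42/42 calculated variables is the
release criterion; any discrepancy is listed record-by-record for
review.  A worksheet export supports the complementary human step —
manual chart reading and guideline review of a random sample of cases.

The oracle below deliberately shares no rule code with
:mod:`cvdrules.engine`: every threshold is a literal, chart cells are
found by interval-containment scan over the raw cell list (not by band
arithmetic), and band labels are formatted locally.  Only the record
and chart *data* containers are shared, since the comparison target is
the input/output contract, not the code path.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass

from .chart import RiskChartSet
from .engine import CALCULATED_VARIABLE_NAMES, NOT_EVALUABLE, RuleThresholds, calculated_variables
from .errors import DomainError
from .records import PATIENT_FIELDS, PatientRecord

__all__ = ["AgreementReport", "oracle_assess", "compare_cohort", "export_review_worksheet"]

_FLOAT_VARS = frozenset({"imputed_chart_age", "tc_mmol", "tc_hdl_ratio", "bmi"})
_FLOAT_TOL = 1e-9


def _fmt_band(lo: float, hi: float) -> str:
    inf = float("inf")
    a = "-inf" if lo == -inf else ("%g" % lo)
    b = "inf" if hi == inf else ("%g" % hi)
    return "[" + a + "," + b + ")"


def _scan_chart(chart_set: RiskChartSet, sex, dm, sm, chart_age, sbp, tc_mmol):
    """Find the cell whose intervals contain the (clamped) inputs by brute scan."""
    inf = float("inf")
    if tc_mmol is None:
        cells = chart_set.low_info_cells
    else:
        cells = chart_set.high_info_cells

    def clamp(value, bounds):
        lo_min = min(b[0] for b in bounds)
        hi_max = max(b[1] for b in bounds)
        v = value
        if lo_min > -inf and v < lo_min:
            v = lo_min
        if hi_max < inf and v >= hi_max:
            v = hi_max - 1e-9
        return v

    age_bounds = sorted({k[3] for k in cells})
    sbp_bounds = sorted({k[4] for k in cells})
    a = clamp(chart_age, age_bounds)
    s = clamp(sbp, sbp_bounds)
    if tc_mmol is not None:
        tc_bounds = sorted({k[5] for k in cells})
        c = clamp(tc_mmol, tc_bounds)
    hits = []
    for key, cat in cells.items():
        if key[0] != sex or key[1] != dm or key[2] != sm:
            continue
        if not (key[3][0] <= a < key[3][1]):
            continue
        if not (key[4][0] <= s < key[4][1]):
            continue
        if tc_mmol is not None and not (key[5][0] <= c < key[5][1]):
            continue
        hits.append((key, cat))
    if len(hits) != 1:
        raise DomainError(f"chart scan found {len(hits)} cells for inputs")
    return hits[0]


def oracle_assess(record: PatientRecord, chart_set: RiskChartSet) -> dict:
    """Independently coded decision table producing the 42-variable vector.

    Flat, sequential re-statement of the plain language rules with
    literal constants throughout.
    """
    NE = "NE"
    r = record

    # --- derived measurements -------------------------------------------
    if r.age < 18 or r.age > 110:
        raise DomainError("age out of range")
    imputed_age = float(r.age)
    if imputed_age < 40:
        imputed_age = 40.0
    if imputed_age > 79:
        imputed_age = 79.0

    bmi = r.weight / ((r.height / 100.0) * (r.height / 100.0))
    tc_mmol = NE if r.tc is None else r.tc / 38.67
    if r.tc is None or r.hdl is None or r.hdl == 0:
        ratio = NE
    else:
        ratio = r.tc / r.hdl

    # --- glucose and diabetes -------------------------------------------
    efg = NE if r.fasting_glucose is None else (r.fasting_glucose >= 126)
    erg = NE if r.random_glucose is None else (r.random_glucose >= 200)
    glucose_any = (efg is True) or (erg is True)
    diabetes = bool(r.hx_diabetes) or (efg is True) or (erg is True)

    # --- chart lookup ----------------------------------------------------
    tc_for_chart = None if r.tc is None else r.tc / 38.67
    if chart_set.cholesterol_units == "mg/dL" and r.tc is not None:
        tc_for_chart = float(r.tc)
    (cell_key, chart_cat) = _scan_chart(
        chart_set, r.sex, diabetes, bool(r.current_smoker), imputed_age, r.sbp, tc_for_chart
    )
    pathway = "low_info" if r.tc is None else "high_info"
    age_band_lbl = _fmt_band(*cell_key[3])
    sbp_band_lbl = _fmt_band(*cell_key[4])
    tc_band_lbl = NE if r.tc is None else _fmt_band(*cell_key[5])

    # --- CVD and clinically-high-risk ------------------------------------
    cvd = bool(r.hx_angina_or_mi) or bool(r.hx_stroke) or bool(r.hx_pvd)
    chr_sbp = r.sbp >= 160
    chr_dbp = r.dbp >= 100
    chr_tc = NE if r.tc is None else (r.tc >= 320)
    chr_ldl = NE if r.ldl is None else (r.ldl >= 240)
    chr_ratio = NE if ratio is NE else (ratio > 8)
    chr_any = chr_sbp or chr_dbp or (chr_tc is True) or (chr_ldl is True) or (chr_ratio is True)

    if cvd and chr_any:
        adjusted = "CVD_AND_CHR"
    elif cvd:
        adjusted = "CVD"
    elif chr_any:
        adjusted = "CHR"
    else:
        adjusted = chart_cat.name

    # ordinal risk gates; override categories are high risk throughout
    band_rank = {"LT10": 0, "R10_20": 1, "R20_30": 2, "R30_40": 3, "GT40": 4}
    high = adjusted in ("CHR", "CVD", "CVD_AND_CHR")
    risk_gt_20 = high or band_rank[adjusted] >= 2
    risk_gt_30 = high or band_rank[adjusted] >= 3
    risk_ge_10_20 = high or band_rank[adjusted] >= 1

    # --- underestimation flags -------------------------------------------
    central = NE
    if r.waist is not None:
        central = r.waist >= (90 if r.sex == "male" else 80)
    obese = (bmi >= 27.5) or (central is True)
    under_bp_med = bool(r.on_bp_lowering)
    under_obesity = obese
    under_fam_hx = bool(r.fam_hx_premature_chd_or_stroke)
    under_tg = NE if r.tg is None else (r.tg > 180)
    under_hdl = NE if r.hdl is None else (r.hdl < (40 if r.sex == "male" else 50))
    under_dys = NE if r.fasting_glucose is None else (110 <= r.fasting_glucose <= 125)
    under_hr = r.heart_rate > 100
    under_any = (
        under_bp_med or under_obesity or under_fam_hx
        or (under_tg is True) or (under_hdl is True) or (under_dys is True) or under_hr
    )

    # --- medication indications ------------------------------------------
    lipid_extreme = (chr_tc is True) or (chr_ldl is True) or (chr_ratio is True)
    bp_160_100 = (r.sbp >= 160) or (r.dbp >= 100)

    bp_med = (
        cvd
        or bp_160_100
        or ((r.sbp >= 140 or r.dbp >= 90) and risk_gt_20)
        or ((r.sbp >= 130 or r.dbp >= 80) and risk_gt_30)
        or lipid_extreme
    )
    statin = (
        cvd
        or diabetes
        or lipid_extreme
        or bp_160_100
        or risk_gt_30
        or (
            r.age >= 40
            and risk_gt_20
            and ((r.tc is not None and r.tc >= 200) or (r.ldl is not None and r.ldl >= 120))
        )
    )
    antiplatelet = cvd or lipid_extreme or bp_160_100 or risk_gt_30

    # --- targets ----------------------------------------------------------
    if cvd or diabetes or lipid_extreme:
        bp_t = (130, 80)
    else:
        bp_t = (140, 90)
    if cvd:
        lipid_t = (160, 80, 45)
    elif diabetes:
        lipid_t = (180, 100, 45)
    else:
        lipid_t = (200, 120, 40)

    # --- referral and lifestyle ------------------------------------------
    referral = (
        risk_gt_20
        or bp_med
        or statin
        or antiplatelet
        or (diabetes and not r.hx_diabetes)
    )
    smoking_advice = bool(r.current_smoker)
    elevated = (
        obese
        or under_any
        or chr_any
        or cvd
        or diabetes
        or smoking_advice
        or risk_ge_10_20
    )
    advice_any = smoking_advice or elevated

    out = {
        "imputed_chart_age": imputed_age,
        "age_band": age_band_lbl,
        "sbp_band": sbp_band_lbl,
        "tc_band": tc_band_lbl,
        "tc_mmol": tc_mmol,
        "tc_hdl_ratio": ratio,
        "bmi": bmi,
        "obesity_flag": obese,
        "central_obesity_flag": central,
        "established_cvd": cvd,
        "atherosclerotic_cvd": cvd,
        "diabetes_status": diabetes,
        "elevated_fasting_glucose": efg,
        "elevated_random_glucose": erg,
        "elevated_glucose_any": glucose_any,
        "chr_sbp": chr_sbp,
        "chr_dbp": chr_dbp,
        "chr_tc": chr_tc,
        "chr_ldl": chr_ldl,
        "chr_ratio": chr_ratio,
        "clinically_high_risk": chr_any,
        "under_bp_med": under_bp_med,
        "under_obesity": under_obesity,
        "under_fam_hx": under_fam_hx,
        "under_tg": under_tg,
        "under_hdl": under_hdl,
        "under_dysglycemia": under_dys,
        "under_heart_rate": under_hr,
        "underestimation_any": under_any,
        "info_pathway": pathway,
        "chart_risk_category": chart_cat.name,
        "adjusted_risk_category": adjusted,
        "bp_med_indicated": bp_med,
        "statin_indicated": statin,
        "antiplatelet_indicated": antiplatelet,
        "bp_target_systolic": bp_t[0],
        "bp_target_diastolic": bp_t[1],
        "tc_target": lipid_t[0],
        "ldl_target": lipid_t[1],
        "hdl_target": lipid_t[2],
        "referral_indicated": referral,
        "lifestyle_advice_any": advice_any,
    }
    assert len(out) == 42
    return out


@dataclass
class AgreementReport:
    n_records: int
    per_variable_agreement: dict
    n_variables_fully_agreeing: int
    discrepancies: list  # (record_id, variable, engine_value, oracle_value)

    @property
    def fully_agrees(self) -> bool:
        return self.n_variables_fully_agreeing == len(self.per_variable_agreement)

    def to_text(self) -> str:
        lines = [
            f"records compared: {self.n_records}",
            f"variables fully agreeing: {self.n_variables_fully_agreeing}"
            f"/{len(self.per_variable_agreement)}",
        ]
        for name, frac in self.per_variable_agreement.items():
            lines.append(f"  {name}: {frac:.4f}")
        if self.discrepancies:
            lines.append("discrepancies (record_id, variable, engine, oracle):")
            for rid, var, ev, ov in self.discrepancies:
                lines.append(f"  {rid}\t{var}\t{ev!r}\t{ov!r}")
        return "\n".join(lines) + "\n"


def _values_agree(name: str, engine_value, oracle_value) -> bool:
    if engine_value is NOT_EVALUABLE or engine_value == NOT_EVALUABLE:
        return oracle_value == NOT_EVALUABLE
    if oracle_value == NOT_EVALUABLE:
        return False
    if name in _FLOAT_VARS or (
        isinstance(engine_value, float) and isinstance(oracle_value, float)
    ):
        return abs(float(engine_value) - float(oracle_value)) <= _FLOAT_TOL
    return engine_value == oracle_value


def compare_cohort(
    records: list[PatientRecord],
    chart_set: RiskChartSet,
    engine_thresholds: RuleThresholds | None = None,
) -> AgreementReport:
    """Run engine and oracle on every record and aggregate agreement.

    *engine_thresholds* overrides the engine's rule constants (fault
    injection for mutation studies); the oracle always applies the
    normative constants.
    """
    if not records:
        raise DomainError("cannot compare an empty cohort")
    thresholds = engine_thresholds if engine_thresholds is not None else RuleThresholds()
    n_agree = {name: 0 for name in CALCULATED_VARIABLE_NAMES}
    discrepancies = []
    for rec in records:
        engine_vals = calculated_variables(rec, chart_set, thresholds)
        oracle_vals = oracle_assess(rec, chart_set)
        for name in CALCULATED_VARIABLE_NAMES:
            if _values_agree(name, engine_vals[name], oracle_vals[name]):
                n_agree[name] += 1
            else:
                discrepancies.append(
                    (rec.participant_id, name, engine_vals[name], oracle_vals[name])
                )
    n = len(records)
    per_var = {name: n_agree[name] / n for name in CALCULATED_VARIABLE_NAMES}
    discrepancies.sort(key=lambda d: (d[0], d[1]))
    return AgreementReport(
        n_records=n,
        per_variable_agreement=per_var,
        n_variables_fully_agreeing=sum(1 for f in per_var.values() if f == 1.0),
        discrepancies=discrepancies,
    )


def export_review_worksheet(
    records: list[PatientRecord],
    chart_set: RiskChartSet,
    k: int,
    seed: int,
    worksheet_path,
    answer_key_path,
) -> list[PatientRecord]:
    """Write a physician-review worksheet of *k* seeded-random cases.

    The worksheet lists raw inputs with blank adjudication columns for
    manual chart reading; the answer key carries the engine's outputs
    for later agreement scoring.  Returns the sampled records.
    """
    if k < 1:
        raise DomainError(f"k must be >= 1, got {k}")
    if k > len(records):
        raise DomainError(f"k={k} exceeds cohort size {len(records)}")
    rng = random.Random(seed)
    sample = rng.sample(records, k)
    review_cols = ["reviewer_risk_category", "reviewer_bp_med", "reviewer_statin",
                   "reviewer_antiplatelet", "reviewer_referral"]
    with open(worksheet_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(list(PATIENT_FIELDS) + review_cols)
        for rec in sample:
            row = rec.to_row()
            w.writerow([row[c] for c in PATIENT_FIELDS] + [""] * len(review_cols))
    with open(answer_key_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["participant_id"] + list(CALCULATED_VARIABLE_NAMES))
        for rec in sample:
            vals = calculated_variables(rec, chart_set)
            w.writerow([rec.participant_id] + [vals[n] for n in CALCULATED_VARIABLE_NAMES])
    return sample
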