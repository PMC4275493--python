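"""Synthetic screening cohorts and the deterministic boundary suite.

:func:`generate_cohort` draws reproducible synthetic screening records
whose marginal risk-factor distributions emulate a rural Indian
community screening population (default parameters follow the
community-screened risk-factor profile: mean age 51.4 y (SD 13.1),
mean SBP 129 mm Hg (SD 22), mean DBP 80 (SD 12), 67% female, 13%
current smokers, 16% angina/MI, 1% stroke, 10% PVD, 14% known
diabetes, 19% on BP-lowering medication).  Point-of-care cholesterol
is only intermittently available in the field, so the four lipid
values are jointly missing with probability ``1 -
p_cholesterol_available``.

:func:`boundary_suite` enumerates a fixed set of records that place
every rule threshold at offsets -1/0/+1 (the TC/HDL ratio at
7.9/8.0/8.1), each history flag as a singleton, and every missingness
pattern of the optional fields — the deterministic stress fixture for
the dual-implementation validation harness.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

import numpy as np

from .errors import DomainError
from .records import PatientRecord

__all__ = ["CohortParams", "generate_cohort", "boundary_suite"]


@dataclass(frozen=True)
class CohortParams:
    """Distribution parameters for synthetic cohort generation."""

    n: int = 1000
    seed: int = 0
    p_female: float = 0.67
    p_smoker: float = 0.13
    p_angina_mi: float = 0.16
    p_stroke: float = 0.01
    p_pvd: float = 0.10
    p_diabetes: float = 0.14
    p_bp_med: float = 0.19
    p_fam_hx: float = 0.10
    age_mean: float = 51.4
    age_sd: float = 13.1
    sbp_mean: float = 129.0
    sbp_sd: float = 22.0
    dbp_mean: float = 80.0
    dbp_sd: float = 12.0
    sbp_age_slope: float = 0.4  # mm Hg per year of age
    p_cholesterol_available: float = 0.3
    # lognormal parameters: (median in natural units, sigma of log)
    tc_median: float = 185.0  # mg/dL
    tc_log_sd: float = 0.20
    hdl_median: float = 42.0  # mg/dL
    hdl_log_sd: float = 0.20
    ldl_median: float = 110.0  # mg/dL
    ldl_log_sd: float = 0.25
    tg_median: float = 140.0  # mg/dL
    tg_log_sd: float = 0.40
    fg_median: float = 100.0  # mg/dL fasting glucose
    fg_log_sd: float = 0.25
    rg_median: float = 125.0  # mg/dL random glucose
    rg_log_sd: float = 0.30

    def __post_init__(self):
        if self.n < 1:
            raise DomainError("n must be >= 1")
        for f in dc_fields(self):
            if f.name.startswith("p_"):
                v = getattr(self, f.name)
                if not 0.0 <= v <= 1.0:
                    raise DomainError(f"{f.name}={v} outside [0, 1]")
        for name in ("age_sd", "sbp_sd", "dbp_sd", "tc_log_sd", "hdl_log_sd",
                     "ldl_log_sd", "tg_log_sd", "fg_log_sd", "rg_log_sd"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0")


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Rejection-sampled truncated normal (bounds are mild, so this is cheap)."""
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def generate_cohort(params: CohortParams) -> list[PatientRecord]:
    """Draw a reproducible synthetic cohort of screening records.

    Pure function of *params* (including the seed): identical
    parameters always produce the identical cohort.  Values are
    clipped into the record's clinical domains.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n = p.n

    age = _truncated_normal(rng, p.age_mean, p.age_sd, 18, 110, n)
    female = rng.random(n) < p.p_female
    smoker = rng.random(n) < p.p_smoker
    angina = rng.random(n) < p.p_angina_mi
    stroke = rng.random(n) < p.p_stroke
    pvd = rng.random(n) < p.p_pvd
    diab = rng.random(n) < p.p_diabetes
    bp_med = rng.random(n) < p.p_bp_med
    fam_hx = rng.random(n) < p.p_fam_hx
    lipid_med = rng.random(n) < 0.01
    apl_med = rng.random(n) < 0.03

    # SBP rises with age at the stated slope; residual SD preserves the
    # stated marginal SD.
    resid_sd = float(np.sqrt(max(p.sbp_sd**2 - (p.sbp_age_slope * p.age_sd) ** 2, 25.0)))
    sbp = p.sbp_mean + p.sbp_age_slope * (age - p.age_mean) + rng.normal(0, resid_sd, n)
    sbp = np.clip(sbp, 70, 260)
    dbp = p.dbp_mean + 0.35 * (sbp - p.sbp_mean) + rng.normal(0, p.dbp_sd * 0.85, n)
    dbp = np.clip(dbp, 40, sbp - 10)
    heart_rate = np.clip(rng.normal(78, 12, n), 40, 180)

    height = np.where(female, rng.normal(155, 8, n), rng.normal(165, 8, n))
    height = np.clip(height, 130, 200)
    bmi = _truncated_normal(rng, 24.2, 4.6, 13, 45, n)
    weight = bmi * (height / 100.0) ** 2
    waist_available = rng.random(n) < 0.8
    waist = np.where(female, 76 + 2.6 * (bmi - 24.2), 84 + 2.8 * (bmi - 24.2))
    waist = np.clip(waist + rng.normal(0, 5, n), 50, 160)

    chol_available = rng.random(n) < p.p_cholesterol_available
    tc = p.tc_median * np.exp(rng.normal(0, p.tc_log_sd, n))
    hdl = p.hdl_median * np.exp(rng.normal(0, p.hdl_log_sd, n))
    ldl = p.ldl_median * np.exp(rng.normal(0, p.ldl_log_sd, n))
    tg = p.tg_median * np.exp(rng.normal(0, p.tg_log_sd, n))

    is_fasting = rng.random(n) < 0.5
    fg = p.fg_median * np.exp(rng.normal(0, p.fg_log_sd, n))
    rg = p.rg_median * np.exp(rng.normal(0, p.rg_log_sd, n))
    # known diabetics run higher glucose
    fg = np.where(diab, fg * 1.5, fg)
    rg = np.where(diab, rg * 1.5, rg)

    records = []
    for i in range(n):
        records.append(
            PatientRecord(
                participant_id=f"S{i + 1:05d}",
                assessment_date="2014-03-01",
                assessor_role="NPHW",
                village_code=f"V{(i % 11) + 1:02d}",
                age=round(float(age[i]), 1),
                sex="female" if female[i] else "male",
                current_smoker=bool(smoker[i]),
                hx_angina_or_mi=bool(angina[i]),
                hx_stroke=bool(stroke[i]),
                hx_pvd=bool(pvd[i]),
                hx_diabetes=bool(diab[i]),
                fam_hx_premature_chd_or_stroke=bool(fam_hx[i]),
                on_bp_lowering=bool(bp_med[i]),
                on_lipid_lowering=bool(lipid_med[i]),
                on_antiplatelet=bool(apl_med[i]),
                sbp=round(float(sbp[i]), 1),
                dbp=round(float(dbp[i]), 1),
                heart_rate=round(float(heart_rate[i]), 1),
                height=round(float(height[i]), 1),
                weight=round(float(weight[i]), 1),
                waist=round(float(waist[i]), 1) if waist_available[i] else None,
                glucose_is_fasting=bool(is_fasting[i]),
                fasting_glucose=round(float(fg[i]), 1) if is_fasting[i] else None,
                random_glucose=round(float(rg[i]), 1) if not is_fasting[i] else None,
                tc=round(float(tc[i]), 1) if chol_available[i] else None,
                ldl=round(float(ldl[i]), 1) if chol_available[i] else None,
                hdl=round(float(hdl[i]), 1) if chol_available[i] else None,
                tg=round(float(tg[i]), 1) if chol_available[i] else None,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Deterministic boundary suite

# (field, values) — each value yields one record varying that field on the base.
_SCALAR_VARIANTS: tuple[tuple[str, tuple], ...] = (
    # chart-band and indication SBP edges, and the CHR threshold
    ("sbp", (129, 130, 131, 139, 140, 141, 159, 160, 161, 179, 180, 181)),
    # DBP indication and CHR edges
    ("dbp", (79, 80, 81, 89, 90, 91, 99, 100, 101)),
    # statin TC gate and CHR TC threshold
    ("tc", (199, 200, 201, 319, 320, 321)),
    # statin LDL gate and CHR LDL threshold
    ("ldl", (119, 120, 121, 239, 240, 241)),
    # raised triglycerides (strict >180)
    ("tg", (179, 180, 181)),
    # heart rate (strict >100)
    ("heart_rate", (99, 100, 101)),
    # fasting glucose: dysglycemia window edges and the diabetes threshold
    ("fasting_glucose", (109, 110, 111, 124, 125, 126, 127)),
    # random glucose diabetes threshold
    ("random_glucose", (199, 200, 201)),
    # age imputation edges (40, 79), chart age-band edges, statin age gate
    ("age", (39, 40, 41, 49, 50, 51, 69, 70, 71, 78, 79, 80)),
)

# TC values giving TC/HDL of 7.9/8.0/8.1 at the base HDL of 40 mg/dL.
_RATIO_TRIPLET: tuple[float, ...] = (316.0, 320.0, 324.0)

# sex-specific HDL cut-offs
_HDL_MALE: tuple[float, ...] = (39, 40, 41)
_HDL_FEMALE: tuple[float, ...] = (49, 50, 51)

# weights giving BMI 27.4/27.5/27.6 at the base height of 160 cm
_BMI_TRIPLET: tuple[float, ...] = (27.4, 27.5, 27.6)

_WAIST_MALE: tuple[float, ...] = (89, 90, 91)
_WAIST_FEMALE: tuple[float, ...] = (79, 80, 81)

_FLAG_SINGLETONS: tuple[str, ...] = (
    "current_smoker", "hx_angina_or_mi", "hx_stroke", "hx_pvd", "hx_diabetes",
    "fam_hx_premature_chd_or_stroke", "on_bp_lowering", "on_lipid_lowering",
    "on_antiplatelet",
)

# each entry: fields reset to None on the base record
_MISSINGNESS_PATTERNS: tuple[tuple[str, ...], ...] = (
    ("tc", "ldl", "hdl", "tg"),
    ("tc",),
    ("ldl",),
    ("hdl",),
    ("tg",),
    ("waist",),
    ("fasting_glucose", "glucose_is_fasting"),
    ("waist", "glucose_is_fasting", "fasting_glucose", "random_glucose",
     "tc", "ldl", "hdl", "tg"),
)

# Compound cases: CVD with extreme BP, high-band chart cells, and BP/lipid
# rule boundaries probed *inside* the risk-band context where the rule is
# decisive (a moderate-BP cut only matters at 20-30% risk, where the
# mild-BP rule does not also fire; the statin lipid gate only matters at
# >20% risk without any other statin criterion).  On the bundled chart an
# older female smoker with borderline cholesterol sits in the 20-30% band
# and, with high cholesterol, in the 30-40% band.
_R20_30_CTX = dict(sex="female", current_smoker=True, age=75, tc=199.0)
_R30_40_CTX = dict(sex="female", current_smoker=True, age=75, tc=280.0)
_COMPOUND_CASES: tuple[dict, ...] = (
    dict(hx_stroke=True, sbp=170, dbp=95),
    dict(hx_angina_or_mi=True, sbp=118, dbp=76),
    dict(age=75, sbp=185, dbp=95, current_smoker=True, hx_diabetes=True, tc=350),
    dict(age=68, sbp=165, dbp=88, current_smoker=True),
    dict(age=62, sbp=150, dbp=92, hx_diabetes=True),
    # moderate BP rule (>=140/90 with risk >20%) boundaries at 20-30% risk
    dict(**_R20_30_CTX, sbp=139),
    dict(**_R20_30_CTX, sbp=140),
    dict(**_R20_30_CTX, sbp=141),
    dict(**_R20_30_CTX, sbp=120, dbp=89),
    dict(**_R20_30_CTX, sbp=120, dbp=90),
    dict(**_R20_30_CTX, sbp=120, dbp=91),
    # mild BP rule (>=130/80 with risk >30%) boundaries at 30-40% risk
    dict(**_R30_40_CTX, sbp=129),
    dict(**_R30_40_CTX, sbp=130),
    dict(**_R30_40_CTX, sbp=131),
    dict(**_R30_40_CTX, sbp=120, dbp=79),
    dict(**_R30_40_CTX, sbp=120, dbp=80),
    dict(**_R30_40_CTX, sbp=120, dbp=81),
    # statin lipid gate (age >=40, risk >20%, TC >=200 or LDL >=120)
    dict(**{**_R20_30_CTX, "tc": 199.0}, sbp=145),
    dict(**{**_R20_30_CTX, "tc": 200.0}, sbp=145),
    dict(**{**_R20_30_CTX, "tc": 201.0}, sbp=145),
    dict(**{**_R20_30_CTX, "tc": 170.0}, sbp=145, ldl=119),
    dict(**{**_R20_30_CTX, "tc": 170.0}, sbp=145, ldl=120),
    dict(**{**_R20_30_CTX, "tc": 170.0}, sbp=145, ldl=121),
)


def _base_record(pid: str) -> PatientRecord:
    """Complete low-risk female record every variant perturbs."""
    return PatientRecord(
        participant_id=pid,
        assessment_date="2014-03-01",
        assessor_role="NPHW",
        village_code="V01",
        age=55,
        sex="female",
        current_smoker=False,
        hx_angina_or_mi=False,
        hx_stroke=False,
        hx_pvd=False,
        hx_diabetes=False,
        fam_hx_premature_chd_or_stroke=False,
        on_bp_lowering=False,
        on_lipid_lowering=False,
        on_antiplatelet=False,
        sbp=120,
        dbp=76,
        heart_rate=72,
        height=160,
        weight=60,
        waist=72,
        glucose_is_fasting=True,
        fasting_glucose=92,
        random_glucose=None,
        tc=180,
        ldl=100,
        hdl=55,
        tg=120,
    )


def boundary_suite() -> list[PatientRecord]:
    """Enumerate the deterministic threshold-boundary records.

    Size is the closed-form count:
    1 base + sum(len(values) per scalar field) + 3 ratio + 2*3 HDL
    + 3 BMI + 2*3 waist + len(flag singletons) + len(missingness
    patterns) + len(compound cases).
    """
    records: list[PatientRecord] = []
    counter = [0]

    def pid() -> str:
        counter[0] += 1
        return f"B{counter[0]:04d}"

    records.append(_base_record(pid()))
    for fname, values in _SCALAR_VARIANTS:
        for v in values:
            records.append(_base_record(pid()).replace(**{fname: float(v)}))
    for tc in _RATIO_TRIPLET:
        records.append(_base_record(pid()).replace(tc=tc, hdl=40.0))
    for hdl in _HDL_MALE:
        records.append(_base_record(pid()).replace(sex="male", hdl=float(hdl)))
    for hdl in _HDL_FEMALE:
        records.append(_base_record(pid()).replace(hdl=float(hdl)))
    for bmi in _BMI_TRIPLET:
        records.append(_base_record(pid()).replace(weight=round(bmi * 1.6 * 1.6, 4)))
    for w in _WAIST_MALE:
        records.append(_base_record(pid()).replace(sex="male", waist=float(w)))
    for w in _WAIST_FEMALE:
        records.append(_base_record(pid()).replace(waist=float(w)))
    for flag in _FLAG_SINGLETONS:
        records.append(_base_record(pid()).replace(**{flag: True}))
    for pattern in _MISSINGNESS_PATTERNS:
        records.append(_base_record(pid()).replace(**{f: None for f in pattern}))
    for case in _COMPOUND_CASES:
        records.append(_base_record(pid()).replace(**case))
    return records
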