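"""Canonical screening record: the 28 raw inputs collected at one visit.

The field enumeration is the package's normative input schema — four
administrative fields, demographics, past history and medication flags,
physical measurements, and optional point-of-care laboratory values.
Optional fields are ``None`` when not measured; an absent value never
triggers a clinical rule downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from typing import Optional

from .errors import DomainError

__all__ = ["PatientRecord", "PATIENT_FIELDS"]


@dataclass(frozen=True)
class PatientRecord:
    participant_id: str
    assessment_date: str  # ISO date text
    assessor_role: str  # "NPHW" | "physician"
    village_code: str
    age: float  # years
    sex: str  # "male" | "female"
    current_smoker: bool
    hx_angina_or_mi: bool
    hx_stroke: bool
    hx_pvd: bool
    hx_diabetes: bool
    fam_hx_premature_chd_or_stroke: bool
    on_bp_lowering: bool
    on_lipid_lowering: bool
    on_antiplatelet: bool
    sbp: float  # mm Hg
    dbp: float  # mm Hg
    heart_rate: float  # beats/min
    height: float  # cm
    weight: float  # kg
    waist: Optional[float] = None  # cm
    glucose_is_fasting: Optional[bool] = None
    fasting_glucose: Optional[float] = None  # mg/dL
    random_glucose: Optional[float] = None  # mg/dL
    tc: Optional[float] = None  # mg/dL
    ldl: Optional[float] = None  # mg/dL
    hdl: Optional[float] = None  # mg/dL
    tg: Optional[float] = None  # mg/dL

    def __post_init__(self):
        if self.assessor_role not in ("NPHW", "physician"):
            raise DomainError(f"assessor_role must be NPHW|physician, got {self.assessor_role!r}")
        if self.sex not in ("male", "female"):
            raise DomainError(f"sex must be male|female, got {self.sex!r}")
        if not 18 <= self.age <= 110:
            raise DomainError(f"age {self.age} outside [18, 110]")
        if not 60 <= self.sbp <= 300:
            raise DomainError(f"sbp {self.sbp} outside [60, 300]")
        if not 30 <= self.dbp <= 200:
            raise DomainError(f"dbp {self.dbp} outside [30, 200]")
        if not self.dbp < self.sbp:
            raise DomainError(f"dbp {self.dbp} must be below sbp {self.sbp}")
        if not 20 <= self.heart_rate <= 250:
            raise DomainError(f"heart_rate {self.heart_rate} outside [20, 250]")
        if self.height <= 0 or self.weight <= 0:
            raise DomainError("height and weight must be positive")
        for name in ("waist", "fasting_glucose", "random_glucose", "tc", "ldl", "hdl", "tg"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise DomainError(f"{name} must be >= 0, got {v}")

    @property
    def bmi(self) -> float:
        """Body-mass index, kg/m^2."""
        return self.weight / (self.height / 100.0) ** 2

    def replace(self, **changes) -> "PatientRecord":
        from dataclasses import replace as _replace

        return _replace(self, **changes)

    def to_row(self) -> dict:
        """Flatten to CSV-friendly strings; missing optionals become ''."""
        row = {}
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if v is None:
                row[f.name] = ""
            elif isinstance(v, bool):
                row[f.name] = "1" if v else "0"
            else:
                row[f.name] = str(v)
        return row

    @classmethod
    def from_row(cls, row: dict) -> "PatientRecord":
        """Parse a CSV row dict (empty string = missing) into a record."""

        def flag(name, optional=False):
            v = (row.get(name) or "").strip().lower()
            if v == "":
                if optional:
                    return None
                raise DomainError(f"required flag {name} is missing")
            if v in ("1", "true", "yes"):
                return True
            if v in ("0", "false", "no"):
                return False
            raise DomainError(f"bad flag value {row[name]!r} for {name}")

        def num(name, optional=False):
            v = (row.get(name) or "").strip()
            if v == "":
                if optional:
                    return None
                raise DomainError(f"required field {name} is missing")
            try:
                return float(v)
            except ValueError:
                raise DomainError(f"bad numeric value {v!r} for {name}") from None

        return cls(
            participant_id=(row.get("participant_id") or "").strip(),
            assessment_date=(row.get("assessment_date") or "").strip(),
            assessor_role=(row.get("assessor_role") or "").strip(),
            village_code=(row.get("village_code") or "").strip(),
            age=num("age"),
            sex=(row.get("sex") or "").strip().lower(),
            current_smoker=flag("current_smoker"),
            hx_angina_or_mi=flag("hx_angina_or_mi"),
            hx_stroke=flag("hx_stroke"),
            hx_pvd=flag("hx_pvd"),
            hx_diabetes=flag("hx_diabetes"),
            fam_hx_premature_chd_or_stroke=flag("fam_hx_premature_chd_or_stroke"),
            on_bp_lowering=flag("on_bp_lowering"),
            on_lipid_lowering=flag("on_lipid_lowering"),
            on_antiplatelet=flag("on_antiplatelet"),
            sbp=num("sbp"),
            dbp=num("dbp"),
            heart_rate=num("heart_rate"),
            height=num("height"),
            weight=num("weight"),
            waist=num("waist", optional=True),
            glucose_is_fasting=flag("glucose_is_fasting", optional=True),
            fasting_glucose=num("fasting_glucose", optional=True),
            random_glucose=num("random_glucose", optional=True),
            tc=num("tc", optional=True),
            ldl=num("ldl", optional=True),
            hdl=num("hdl", optional=True),
            tg=num("tg", optional=True),
        )


#: Canonical CSV column order for patient input files.
PATIENT_FIELDS: tuple[str, ...] = tuple(f.name for f in dc_fields(PatientRecord))

assert len(PATIENT_FIELDS) == 28
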