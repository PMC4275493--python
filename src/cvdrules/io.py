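"""File-format plumbing: patient CSV, assessment output, follow-ups, config.

All tabular files are comma-separated with a mandatory header row.
Empty fields mean "not measured".  Output files begin with comment
lines (``# key=value``) embedding the tool version, chart label, and a
hash of the run configuration, so any result file can be traced back
to the exact run that produced it.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass

import yaml

from . import __version__
from .cascade import FollowUpRecord
from .engine import CALCULATED_VARIABLE_NAMES, AssessedPatient
from .errors import DomainError
from .records import PATIENT_FIELDS, PatientRecord

__all__ = [
    "RowError",
    "read_patient_csv",
    "write_patient_csv",
    "write_assessment_csv",
    "read_followup_csv",
    "write_agreement_csv",
    "config_hash",
    "header_lines",
    "load_config",
]


@dataclass(frozen=True)
class RowError:
    line_number: int
    message: str


def config_hash(config: dict) -> str:
    """Short stable hash of a run configuration."""
    text = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def header_lines(chart_label: str, config: dict) -> list[str]:
    return [
        f"# cvdrules version={__version__}",
        f"# chart={chart_label}",
        f"# config_hash={config_hash(config)}",
    ]


def _open_rows(path):
    """Yield (line_number, row) for non-comment CSV lines."""
    with open(path, newline="") as fh:
        header = None
        for lineno, raw in enumerate(csv.reader(fh), start=1):
            if not raw or raw[0].startswith("#"):
                continue
            if header is None:
                header = [c.strip() for c in raw]
                yield lineno, ("__header__", header)
                continue
            yield lineno, (header, raw)


def read_patient_csv(path) -> tuple[list[PatientRecord], list[RowError]]:
    """Read a patient input file, tolerating malformed rows.

    Field data entry is error-prone, so a bad row is reported (with
    its line number) and skipped rather than aborting the run.
    """
    records: list[PatientRecord] = []
    errors: list[RowError] = []
    header: list[str] | None = None
    for lineno, (h, row) in _open_rows(path):
        if h == "__header__":
            header = row
            missing = set(PATIENT_FIELDS) - set(header)
            if missing:
                raise DomainError(f"patient file missing columns: {sorted(missing)}")
            continue
        try:
            records.append(PatientRecord.from_row(dict(zip(header, row))))
        except (DomainError, ValueError) as exc:
            errors.append(RowError(lineno, str(exc)))
    return records, errors


def write_patient_csv(records: list[PatientRecord], path, chart_label="", config=None) -> None:
    with open(path, "w", newline="") as fh:
        for line in header_lines(chart_label, config or {}):
            fh.write(line + "\n")
        w = csv.writer(fh)
        w.writerow(PATIENT_FIELDS)
        for rec in records:
            row = rec.to_row()
            w.writerow([row[c] for c in PATIENT_FIELDS])


_REASON_COLUMNS = ("chr_reasons", "underestimation_flags", "bp_med_reasons",
                   "statin_reasons", "antiplatelet_reasons", "lifestyle_advice")


def write_assessment_csv(assessed: list[AssessedPatient], path, chart_label="", config=None) -> None:
    """One row per patient: id, the 42 calculated variables, reason codes."""
    with open(path, "w", newline="") as fh:
        for line in header_lines(chart_label, config or {}):
            fh.write(line + "\n")
        w = csv.writer(fh)
        w.writerow(["participant_id", *CALCULATED_VARIABLE_NAMES, *_REASON_COLUMNS])
        for a in assessed:
            reasons = [
                ";".join(sorted(a.assessment.chr_reasons)),
                ";".join(sorted(a.assessment.underestimation_flags)),
                ";".join(a.plan.bp_med_reasons),
                ";".join(a.plan.statin_reasons),
                ";".join(a.plan.antiplatelet_reasons),
                ";".join(sorted(a.plan.lifestyle_advice)),
            ]
            w.writerow(
                [a.record.participant_id]
                + [a.calculated[n] for n in CALCULATED_VARIABLE_NAMES]
                + reasons
            )


def write_patient_report(assessed: AssessedPatient, fh) -> None:
    """Structured single-patient report in key: value form."""
    a = assessed
    fh.write(f"participant_id: {a.record.participant_id}\n")
    fh.write(f"adjusted_risk_category: {a.assessment.adjusted_category}\n")
    fh.write(f"chart_risk_category: {a.assessment.chart_category.name}\n")
    fh.write(f"pathway: {a.assessment.pathway}\n")
    fh.write(f"chr_reasons: {';'.join(sorted(a.assessment.chr_reasons)) or '-'}\n")
    fh.write(
        "underestimation_flags: "
        f"{';'.join(sorted(a.assessment.underestimation_flags)) or '-'}\n"
    )
    fh.write(f"bp_med_indicated: {a.plan.bp_med_indicated}\n")
    fh.write(f"statin_indicated: {a.plan.statin_indicated}\n")
    fh.write(f"antiplatelet_indicated: {a.plan.antiplatelet_indicated}\n")
    fh.write(f"bp_target: <{a.plan.bp_target[0]}/{a.plan.bp_target[1]} mm Hg\n")
    tc_t, ldl_t, hdl_t = a.plan.lipid_targets
    fh.write(f"lipid_targets: TC<{tc_t} LDL<{ldl_t} HDL>{hdl_t} mg/dL\n")
    fh.write(f"referral_indicated: {a.plan.referral_indicated}\n")
    fh.write(f"lifestyle_advice: {';'.join(sorted(a.plan.lifestyle_advice)) or '-'}\n")


_FOLLOWUP_FIELDS = ("participant_id", "visited_doctor_within_1_month", "provider_type",
                    "medication_recommended", "on_medication_at_3_months")


def read_followup_csv(path) -> list[FollowUpRecord]:
    def flag(v):
        return (v or "").strip().lower() in ("1", "true", "yes")

    out = []
    header = None
    for lineno, (h, row) in _open_rows(path):
        if h == "__header__":
            header = row
            missing = set(_FOLLOWUP_FIELDS) - set(header)
            if missing:
                raise DomainError(f"follow-up file missing columns: {sorted(missing)}")
            continue
        d = dict(zip(header, row))
        out.append(
            FollowUpRecord(
                participant_id=d["participant_id"].strip(),
                visited_doctor_within_1_month=flag(d["visited_doctor_within_1_month"]),
                provider_type=(d["provider_type"] or "none").strip() or "none",
                medication_recommended=flag(d["medication_recommended"]),
                on_medication_at_3_months=flag(d["on_medication_at_3_months"]),
            )
        )
    return out


def write_agreement_csv(report, path, chart_label="", config=None) -> None:
    with open(path, "w", newline="") as fh:
        for line in header_lines(chart_label, config or {}):
            fh.write(line + "\n")
        w = csv.writer(fh)
        w.writerow(["variable", "agreement_fraction"])
        for name, frac in report.per_variable_agreement.items():
            w.writerow([name, f"{frac:.6f}"])


def load_config(path) -> dict:
    """Load a YAML-style key-value config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise DomainError("config file must contain a mapping")
    return data
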