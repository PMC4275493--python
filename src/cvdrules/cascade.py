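"""Care-cascade analytics: screening -> referral -> attendance -> treatment.

The cascade counts how many screened adults were flagged for referral,
how many of those had a definite indication for BP-lowering
medication, how many attended a clinic within one month, how many were
recommended medication by the treating doctor, and how many still
reported taking it at three months.  Stage percentages are always
taken over the immediately preceding stage (no re-basing) and printed
as integers rounded half-up, matching field-report conventions.

A separate clinic-side summary reports BP management among
physician-screened patients: the fraction already on BP-lowering
therapy, the fraction of those at their assigned BP target, and the
fraction of untreated patients the algorithm recommends for treatment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .engine import AssessedPatient
from .errors import DomainError, JoinError

__all__ = [
    "FollowUpRecord",
    "CascadeCounts",
    "BPManagementSummary",
    "round_percent",
    "compute_cascade",
    "bp_management_summary",
    "is_pvd_only_high_risk",
]


def round_percent(numerator: int, denominator: int) -> int:
    """Integer percentage, rounded half-up."""
    if denominator == 0:
        return 0
    return int(math.floor(100.0 * numerator / denominator + 0.5))


@dataclass(frozen=True)
class FollowUpRecord:
    participant_id: str
    visited_doctor_within_1_month: bool
    provider_type: str  # government | private | none
    medication_recommended: bool
    on_medication_at_3_months: bool

    def __post_init__(self):
        if self.provider_type not in ("government", "private", "none"):
            raise DomainError(
                f"provider_type must be government|private|none, got {self.provider_type!r}"
            )
        if self.medication_recommended and not self.visited_doctor_within_1_month:
            raise DomainError(
                f"{self.participant_id}: medication_recommended requires a doctor visit"
            )
        if self.on_medication_at_3_months and not self.medication_recommended:
            raise DomainError(
                f"{self.participant_id}: on_medication_at_3_months requires a recommendation"
            )


_STAGES = ("screened", "referred", "bp_med_indicated", "attended_1_month",
           "recommended", "adherent_3_months")


@dataclass(frozen=True)
class CascadeCounts:
    screened: int
    referred: int
    bp_med_indicated: int
    attended_1_month: int
    recommended: Optional[int]  # None when the doctor-recommendation stage was not captured
    adherent_3_months: int

    def __post_init__(self):
        chain = [self.screened, self.referred, self.bp_med_indicated, self.attended_1_month]
        if self.recommended is not None:
            chain.append(self.recommended)
        chain.append(self.adherent_3_months)
        for a, b in zip(chain, chain[1:]):
            if b > a:
                raise DomainError(f"cascade counts must be non-increasing, got {chain}")

    @property
    def stage_percentages(self) -> list[tuple[str, str, int]]:
        """(numerator stage, denominator stage, integer percent) per link.

        Each denominator is the preceding stage's count.  When the
        doctor-recommendation stage was not captured, adherence is
        taken over attendance.
        """
        stages = [(s, getattr(self, s)) for s in _STAGES]
        if self.recommended is None:
            stages = [s for s in stages if s[0] != "recommended"]
        out = []
        for (dname, dval), (nname, nval) in zip(stages, stages[1:]):
            out.append((nname, dname, round_percent(nval, dval)))
        return out

    def to_text(self) -> str:
        lines = []
        for s in _STAGES:
            v = getattr(self, s)
            lines.append(f"{s}: {'-' if v is None else v}")
        for num, den, pct in self.stage_percentages:
            lines.append(f"{num}/{den}: {pct}%")
        return "\n".join(lines) + "\n"


def is_pvd_only_high_risk(assessed: AssessedPatient) -> bool:
    """High-risk classification resting on a reported PVD history alone.

    Field NPHWs can over-report PVD (leg pain read as disease), so a
    record is flagged PVD-only when the history shows PVD without
    angina/MI or stroke, no extreme single risk factor, and a chart
    band below 20-30% — i.e. nothing else suggests high risk.
    """
    rec = assessed.record
    a = assessed.assessment
    return (
        rec.hx_pvd
        and not (rec.hx_angina_or_mi or rec.hx_stroke)
        and a.adjusted_category == "CVD"
        and not a.chr_reasons
        and int(a.chart_category) < 2  # below the 20-30% band
    )


def compute_cascade(
    assessed: list[AssessedPatient],
    followups: list[FollowUpRecord],
    exclude_pvd_only: bool = False,
) -> CascadeCounts:
    """Aggregate the care cascade from engine output plus follow-up records.

    Follow-ups must join to assessments by participant id; orphans are
    rejected.  ``exclude_pvd_only`` drops records whose high-risk
    status rests on reported PVD alone before counting.
    """
    if not assessed:
        raise DomainError("no assessments supplied")
    ids = {a.record.participant_id for a in assessed}
    orphans = [f.participant_id for f in followups if f.participant_id not in ids]
    if orphans:
        raise JoinError(orphans)
    fu_by_id = {f.participant_id: f for f in followups}

    if exclude_pvd_only:
        assessed = [a for a in assessed if not is_pvd_only_high_risk(a)]

    screened = len(assessed)
    referred = [a for a in assessed if a.plan.referral_indicated]
    indicated = [a for a in referred if a.plan.bp_med_indicated]
    attended = [
        a for a in indicated
        if (f := fu_by_id.get(a.record.participant_id)) is not None
        and f.visited_doctor_within_1_month
    ]
    recommended = [
        a for a in attended if fu_by_id[a.record.participant_id].medication_recommended
    ]
    adherent = [
        a for a in recommended if fu_by_id[a.record.participant_id].on_medication_at_3_months
    ]
    return CascadeCounts(
        screened=screened,
        referred=len(referred),
        bp_med_indicated=len(indicated),
        attended_1_month=len(attended),
        recommended=len(recommended),
        adherent_3_months=len(adherent),
    )


@dataclass(frozen=True)
class BPManagementSummary:
    n: int
    n_on_bp_med: int
    pct_on_bp_med: int
    n_at_target_among_treated: int
    pct_at_target_among_treated: int
    n_untreated: int
    n_untreated_indicated: int
    pct_untreated_indicated: int

    def to_text(self) -> str:
        return (
            f"patients assessed: {self.n}\n"
            f"already on BP-lowering medication: {self.n_on_bp_med} ({self.pct_on_bp_med}%)\n"
            f"of those, at BP target: {self.n_at_target_among_treated} "
            f"({self.pct_at_target_among_treated}%)\n"
            f"not on medication: {self.n_untreated}\n"
            f"of those, BP-lowering indicated: {self.n_untreated_indicated} "
            f"({self.pct_untreated_indicated}%)\n"
        )


def bp_management_summary(assessed: list[AssessedPatient]) -> BPManagementSummary:
    """Clinic-side BP management summary.

    "At target" means SBP strictly below the patient's assigned
    systolic target AND DBP strictly below the diastolic target.
    """
    if not assessed:
        raise DomainError("no assessments supplied")
    treated = [a for a in assessed if a.record.on_bp_lowering]
    untreated = [a for a in assessed if not a.record.on_bp_lowering]
    at_target = [
        a for a in treated
        if a.record.sbp < a.plan.bp_target[0] and a.record.dbp < a.plan.bp_target[1]
    ]
    indicated = [a for a in untreated if a.plan.bp_med_indicated]
    return BPManagementSummary(
        n=len(assessed),
        n_on_bp_med=len(treated),
        pct_on_bp_med=round_percent(len(treated), len(assessed)),
        n_at_target_among_treated=len(at_target),
        pct_at_target_among_treated=round_percent(len(at_target), len(treated)),
        n_untreated=len(untreated),
        n_untreated_indicated=len(indicated),
        pct_untreated_indicated=round_percent(len(indicated), len(untreated)),
    )
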