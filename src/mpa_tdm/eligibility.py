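"""Study eligibility rules, renal-function screen, and flare-based outcomes.

The eligibility screen mirrors a maintenance-therapy SLE PK study: patients
with active renal involvement, renal impairment (Cockcroft-Gault creatinine
clearance < 60 mL/min), hepatic dysfunction, interacting co-medication, or
an MMF dose outside the 1-3 g/day maintenance range are not analyzable.

A clinical flare is a rise of at least 3 SLEDAI points between two
consecutive monthly visits; patients who flare are labelled failures with
the month of the first qualifying rise, patients who discontinue therapy
are excluded, everyone else is a success.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import DomainError, InsufficientDataError, ValidationError
from .model import Cohort, OutcomeLabel, PatientRecord

#: minimum Cockcroft-Gault clearance (mL/min) for inclusion
GFR_THRESHOLD = 60.0
#: maintenance dose range (g/day) at inclusion
DOSE_RANGE = (1.0, 3.0)
#: minimum SLEDAI rise between consecutive visits that qualifies as a flare
FLARE_DELTA = 3


@dataclass
class EligibilityResult:
    patient_id: str
    eligible: bool
    reasons: list[str] = field(default_factory=list)


def cockcroft_gault(age: float, weight: float, serum_creatinine: float,
                    sex: str) -> float:
    """Cockcroft-Gault creatinine clearance in mL/min.

    ``((140 - age) * weight / (72 * serum_creatinine))``, multiplied by 0.85
    for women. Age in years, weight in kg, creatinine in mg/dL.
    """
    if serum_creatinine <= 0:
        raise DomainError("serum creatinine must be positive")
    if weight <= 0:
        raise DomainError("weight must be positive")
    if age <= 0:
        raise DomainError("age must be positive")
    sex_factor = 0.85 if sex == "female" else 1.0
    return (140.0 - age) * weight / (72.0 * serum_creatinine) * sex_factor


def check_eligibility(patient: PatientRecord) -> EligibilityResult:
    """Apply every inclusion rule; reasons list all violated rules."""
    reasons: list[str] = []
    gfr = patient.gfr
    if gfr is None:
        try:
            gfr = cockcroft_gault(patient.age, patient.weight,
                                  patient.serum_creatinine, patient.sex)
        except DomainError:
            reasons.append("gfr_indeterminate")
            gfr = None
    if gfr is not None and gfr < GFR_THRESHOLD:
        reasons.append("gfr_below_60")
    if patient.proteinuria_over_0_5g:
        reasons.append("active_renal_involvement")
    if patient.hepatic_dysfunction:
        reasons.append("hepatic_dysfunction")
    if patient.forbidden_comedication:
        reasons.append("forbidden_comedication")
    if not (DOSE_RANGE[0] <= patient.mmf_dose <= DOSE_RANGE[1]):
        reasons.append("dose_out_of_range")
    return EligibilityResult(patient.patient_id, eligible=not reasons,
                             reasons=reasons)


def detect_flare(sledai_by_month: Sequence[int]) -> Optional[int]:
    """Earliest month m >= 1 with a SLEDAI rise >= 3 vs the previous visit.

    The sequence starts at month 0 (inclusion) with consecutive monthly
    entries. Returns ``None`` when no visit qualifies. The rise is measured
    against the *previous* visit, not baseline, so the rule is invariant to
    adding a constant to every score.
    """
    if len(sledai_by_month) < 2:
        raise InsufficientDataError("flare detection needs at least 2 visits")
    for m in range(1, len(sledai_by_month)):
        if sledai_by_month[m] - sledai_by_month[m - 1] >= FLARE_DELTA:
            return m
    return None


def classify_outcomes(cohort: Cohort,
                      discontinued: Optional[Iterable[str]] = None,
                      ) -> list[OutcomeLabel]:
    """Label every patient success / failure / excluded.

    ``discontinued`` lists patient_ids who stopped therapy (intolerance or
    non-compliance); exclusion takes precedence over any flare, since an
    excluded patient never enters the PK-PD analysis. Failures carry the
    month of the first qualifying flare. Labels partition the cohort.
    """
    discontinued = set(discontinued or ())
    labels: list[OutcomeLabel] = []
    for patient in cohort.patients:
        pid = patient.patient_id
        if pid in discontinued:
            labels.append(OutcomeLabel(pid, "excluded",
                                       exclusion_reason="treatment_discontinuation"))
            continue
        visits = cohort.visits_for(pid)
        if not visits or visits[0].month != 0:
            raise ValidationError(f"{pid}: month 0 (inclusion) visit missing")
        flare = detect_flare([v.sledai for v in visits])
        if flare is not None:
            labels.append(OutcomeLabel(pid, "failure",
                                       flare_month=visits[flare].month))
        else:
            labels.append(OutcomeLabel(pid, "success"))
    return labels
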