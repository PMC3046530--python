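"""In-memory data model for a therapeutic-drug-monitoring cohort.

A cohort bundles four tables: patient characteristics at inclusion, the
concentration-time samples of MPA (mycophenolic acid) and its glucuronide
MPAG over one 12-hour dosing interval, monthly SLEDAI/prednisone visits,
and (optionally) the success / failure / excluded outcome labels.

All records are plain dataclasses; `Cohort.validate()` enforces every
cross-table invariant and raises :class:`~mpa_tdm.errors.ValidationError`
naming the offending patient and rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError

ANALYTES = ("MPA", "MPAG")
SEXES = ("female", "male")
OUTCOME_LABELS = ("success", "failure", "excluded")

#: blood-sampling schedule used throughout: pre-dose and 0.5, 1, 2, 3, 4,
#: 6, 8 and 12 hours after the morning MMF dose.
STANDARD_SCHEDULE = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0)


def _finite(x) -> bool:
    return x is not None and math.isfinite(x)


@dataclass
class PatientRecord:
    """Inclusion characteristics of one patient.

    Units: age in years, weight in kg, serum creatinine in mg/dL, albumin /
    C3 / C4 in g/L, anti-dsDNA in IU/mL, GFR in mL/min, MMF dose in g/day,
    prednisone in mg/day, therapy durations in months.
    """

    patient_id: str
    sex: str
    age: float
    weight: float
    serum_creatinine: float
    albumin: Optional[float] = None
    c3: Optional[float] = None
    c4: Optional[float] = None
    anti_dsdna: Optional[float] = None
    gfr: Optional[float] = None
    mmf_dose: float = 2.0
    prednisone_dose: float = 0.0
    months_on_mmf: Optional[float] = None
    months_on_steroids: Optional[float] = None
    sledai_entry: int = 0
    proteinuria_over_0_5g: bool = False
    hepatic_dysfunction: bool = False
    forbidden_comedication: bool = False

    def validate(self) -> None:
        pid = self.patient_id
        if not pid:
            raise ValidationError("patient with empty patient_id")
        if self.sex not in SEXES:
            raise ValidationError(f"{pid}: sex must be one of {SEXES}, got {self.sex!r}")
        for name, value in (("age", self.age), ("weight", self.weight),
                            ("serum_creatinine", self.serum_creatinine)):
            if not _finite(value) or value <= 0:
                raise ValidationError(f"{pid}: {name} must be a positive finite number")
        if not (0.5 <= self.mmf_dose <= 5):
            raise ValidationError(f"{pid}: mmf_dose {self.mmf_dose} outside [0.5, 5] g/day")
        if self.prednisone_dose < 0:
            raise ValidationError(f"{pid}: prednisone_dose must be non-negative")
        if self.sledai_entry < 0:
            raise ValidationError(f"{pid}: sledai_entry must be >= 0")


@dataclass
class ConcProfile:
    """One patient x analyte concentration-time series over 0-12 h."""

    patient_id: str
    analyte: str
    times: np.ndarray  # hours
    concentrations: np.ndarray  # mg/L

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)

    def validate(self) -> None:
        pid = self.patient_id
        if self.analyte not in ANALYTES:
            raise ValidationError(f"{pid}: analyte must be MPA or MPAG, got {self.analyte!r}")
        t, c = self.times, self.concentrations
        if t.shape != c.shape or t.ndim != 1:
            raise ValidationError(f"{pid}/{self.analyte}: times and concentrations must be 1-d and equal length")
        if t.size < 2:
            raise ValidationError(f"{pid}/{self.analyte}: profile needs at least 2 points")
        if np.any(np.diff(t) <= 0):
            raise ValidationError(f"{pid}/{self.analyte}: times must be strictly increasing (one value per time)")
        if t[0] < 0 or t[-1] > 12 + 1e-9:
            raise ValidationError(f"{pid}/{self.analyte}: times must lie within [0, 12] h")
        if abs(t[0]) > 1e-9:
            raise ValidationError(f"{pid}/{self.analyte}: first sample must be the pre-dose (t = 0) sample")
        if np.any(~np.isfinite(c)) or np.any(c < 0):
            bad = int(np.flatnonzero(~np.isfinite(c) | (c < 0))[0])
            raise ValidationError(
                f"{pid}/{self.analyte}: negative or non-finite concentration at t={t[bad]} h")


@dataclass
class VisitRecord:
    """One monthly follow-up visit (month 0 = inclusion)."""

    patient_id: str
    month: int
    sledai: int
    prednisone_dose: float

    def validate(self) -> None:
        pid = self.patient_id
        if not (0 <= self.month <= 6):
            raise ValidationError(f"{pid}: visit month {self.month} outside 0..6")
        if self.sledai < 0:
            raise ValidationError(f"{pid}: SLEDAI must be >= 0")
        if self.prednisone_dose < 0:
            raise ValidationError(f"{pid}: prednisone_dose must be non-negative")


@dataclass
class OutcomeLabel:
    """Success / failure / excluded label with flare month or exclusion reason."""

    patient_id: str
    label: str
    flare_month: Optional[int] = None
    exclusion_reason: Optional[str] = None

    def validate(self) -> None:
        pid = self.patient_id
        if self.label not in OUTCOME_LABELS:
            raise ValidationError(f"{pid}: label must be one of {OUTCOME_LABELS}")
        if (self.label == "failure") != (self.flare_month is not None):
            raise ValidationError(f"{pid}: flare_month present iff label is 'failure'")
        if (self.label == "excluded") != (self.exclusion_reason is not None):
            raise ValidationError(f"{pid}: exclusion_reason present iff label is 'excluded'")
        if self.flare_month is not None and not (1 <= self.flare_month <= 6):
            raise ValidationError(f"{pid}: flare_month {self.flare_month} outside 1..6")


@dataclass
class Cohort:
    """A complete cohort: patients, PK profiles, visits and optional outcomes."""

    patients: list[PatientRecord] = field(default_factory=list)
    profiles: list[ConcProfile] = field(default_factory=list)
    visits: list[VisitRecord] = field(default_factory=list)
    outcomes: Optional[list[OutcomeLabel]] = None

    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]

    def profiles_for(self, patient_id: str) -> dict[str, ConcProfile]:
        return {p.analyte: p for p in self.profiles if p.patient_id == patient_id}

    def visits_for(self, patient_id: str) -> list[VisitRecord]:
        return sorted((v for v in self.visits if v.patient_id == patient_id),
                      key=lambda v: v.month)

    def validate(self, require_profiles: bool = True) -> "Cohort":
        ids = set()
        for p in self.patients:
            p.validate()
            if p.patient_id in ids:
                raise ValidationError(f"{p.patient_id}: duplicate patient_id")
            ids.add(p.patient_id)
        seen: dict[tuple[str, str], int] = {}
        for prof in self.profiles:
            prof.validate()
            if prof.patient_id not in ids:
                raise ValidationError(f"{prof.patient_id}: profile for unknown patient")
            key = (prof.patient_id, prof.analyte)
            seen[key] = seen.get(key, 0) + 1
            if seen[key] > 1:
                raise ValidationError(f"{prof.patient_id}: more than one {prof.analyte} profile")
        if require_profiles:
            for pid in ids:
                for analyte in ANALYTES:
                    if (pid, analyte) not in seen:
                        raise ValidationError(f"{pid}: missing {analyte} profile")
        months: dict[str, set[int]] = {}
        for v in self.visits:
            v.validate()
            if v.patient_id not in ids:
                raise ValidationError(f"{v.patient_id}: visit for unknown patient")
            ms = months.setdefault(v.patient_id, set())
            if v.month in ms:
                raise ValidationError(f"{v.patient_id}: duplicate visit month {v.month}")
            ms.add(v.month)
        for pid, ms in months.items():
            if 0 not in ms:
                raise ValidationError(f"{pid}: month 0 (inclusion) visit missing")
        if self.outcomes is not None:
            seen_out = set()
            for o in self.outcomes:
                o.validate()
                if o.patient_id not in ids:
                    raise ValidationError(f"{o.patient_id}: outcome for unknown patient")
                if o.patient_id in seen_out:
                    raise ValidationError(f"{o.patient_id}: duplicate outcome label")
                seen_out.add(o.patient_id)
        return self


def profile_from_arrays(patient_id: str, analyte: str,
                        times: Sequence[float], conc: Sequence[float]) -> ConcProfile:
    """Convenience constructor that validates immediately."""
    prof = ConcProfile(patient_id, analyte, np.asarray(times), np.asarray(conc))
    prof.validate()
    return prof
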