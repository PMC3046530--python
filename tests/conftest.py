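import numpy as np
import pytest

from mpa_tdm.model import (Cohort, ConcProfile, OutcomeLabel, PatientRecord,
                           STANDARD_SCHEDULE, VisitRecord)

SCHEDULE = np.array(STANDARD_SCHEDULE)


def make_patient(pid, sex="female", age=40.0, weight=60.0, scr=0.8, **kw):
    defaults = dict(albumin=40.0, c3=1.0, c4=0.2, anti_dsdna=20.0, gfr=95.0,
                    mmf_dose=2.0, prednisone_dose=10.0, months_on_mmf=2.0,
                    months_on_steroids=10.0, sledai_entry=0)
    defaults.update(kw)
    return PatientRecord(patient_id=pid, sex=sex, age=age, weight=weight,
                         serum_creatinine=scr, **defaults)


def make_profile(pid, analyte, conc):
    return ConcProfile(pid, analyte, SCHEDULE.copy(),
                       np.asarray(conc, dtype=float))


#: a typical post-dose MPA shape on the 9-point schedule
MPA_SHAPE = [1.0, 8.0, 16.0, 10.0, 6.0, 4.0, 2.5, 1.8, 1.2]
MPAG_SHAPE = [30.0, 45.0, 70.0, 90.0, 80.0, 65.0, 50.0, 40.0, 32.0]


def flat_visits(pid, sledai=0, months=7, prednisone=10.0):
    return [VisitRecord(pid, m, sledai, prednisone) for m in range(months)]


@pytest.fixture
def small_cohort():
    """Three patients with full profiles, visits, and outcomes."""
    patients = [make_patient("A"), make_patient("B", sex="male"),
                make_patient("C")]
    profiles = []
    for pid, scale in [("A", 1.0), ("B", 0.6), ("C", 1.4)]:
        profiles.append(make_profile(pid, "MPA",
                                     [c * scale for c in MPA_SHAPE]))
        profiles.append(make_profile(pid, "MPAG",
                                     [c * scale for c in MPAG_SHAPE]))
    visits = flat_visits("A") + flat_visits("C")
    # B flares at month 3 (0,0,2,6,...): rise of 4 vs previous visit
    b_scores = [0, 0, 2, 6, 6, 6, 6]
    visits += [VisitRecord("B", m, s, 10.0) for m, s in enumerate(b_scores)]
    outcomes = [OutcomeLabel("A", "success"),
                OutcomeLabel("B", "failure", flare_month=3),
                OutcomeLabel("C", "success")]
    return Cohort(patients, profiles, visits, outcomes).validate()
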