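"""Synthetic steady-state MPA/MPAG cohort generator.

Generates cohorts with the statistical structure the analysis pipeline
assumes, so every stage can be exercised and power-tested without patient
data.

PK model
--------
MPA follows a one-compartment model with first-order absorption at periodic
steady state (dosing interval tau = 12 h). Enterohepatic recirculation
(EHC) is modelled by splitting the absorbed dose: a fraction
``ehc_fraction`` of each dose is re-absorbed ``ehc_lag`` hours after
intake, producing the secondary concentration bump characteristic of MPA
while preserving the mass balance AUC_ss = dose_per_interval / (CL/F).
MPAG is the first-order metabolite (formation fraction ``fm``) with its
own clearance and volume, evaluated from the closed-form steady-state
solution. Between-patient variability is lognormal on CL/F, V/F, ka and
the metabolite clearance; residual assay error is multiplicative lognormal
per sample.

Outcome model
-------------
The flare probability is logistic in log trough exposure,
``P(flare) = expit(beta0 + beta1 * ln C12h)`` with the model (noise-free)
trough; ``beta0`` is calibrated by root-finding so the population flare
rate hits ``target_flare_rate``. Flare months are drawn from a weighted
distribution peaked late in follow-up; SLEDAI trajectories are constructed
to encode exactly the assigned flare month (a >= 3-point jump), successes
stay within +/-1 point.

Reproducibility: one master seed drives three documented child streams, in
order patients -> profiles -> outcomes; identical configs give
byte-identical cohort CSVs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .errors import CalibrationError, DomainError
from .model import (Cohort, ConcProfile, OutcomeLabel, PatientRecord,
                    STANDARD_SCHEDULE, VisitRecord)
from .eligibility import cockcroft_gault

TAU = 12.0  # dosing interval, h


@dataclass
class PkConfig:
    """Structural PK parameters (per-F apparent values, medians)."""

    ka: float = 1.5              # 1/h, absorption rate constant
    cl_f_median: float = 15.4    # L/h, apparent MPA clearance
    v_f_median: float = 90.0     # L, apparent MPA volume (sets the trough)
    ehc_fraction: float = 0.15   # dose fraction re-absorbed via EHC
    ehc_lag: float = 6.0         # h, delay of the EHC re-absorption


@dataclass
class MpagConfig:
    fm: float = 0.95             # fraction of MPA converted to MPAG
    cl_m_over_f: float = 1.22    # L/h, apparent MPAG clearance (AUC ratio ~12)
    v_m_over_f: float = 0.8      # L, apparent MPAG volume (sets MPAG trough)


@dataclass
class BsvConfig:
    """Between-subject variability as lognormal CVs."""

    cl: float = 0.40
    v: float = 0.30
    ka: float = 0.30
    cl_m: float = 0.40


@dataclass
class OutcomeConfig:
    beta1: float = -2.5            # slope on ln C12h (negative: low trough -> flare)
    beta0: Optional[float] = None  # intercept; None -> calibrated
    target_flare_rate: float = 0.31
    discontinuation_rate: float = 1.0 / 26.0
    flare_month_weights: tuple = (0.04, 0.06, 0.10, 0.20, 0.30, 0.30)


@dataclass
class SimConfig:
    n_patients: int = 26
    dose_g_day: float = 2.0
    #: empirical daily-dose mixture used by simulate_cohort
    dose_choices: tuple = (2.0, 1.0, 3.0, 1.5)
    dose_probs: tuple = (21 / 26, 2 / 26, 2 / 26, 1 / 26)
    pk: PkConfig = field(default_factory=PkConfig)
    mpag: MpagConfig = field(default_factory=MpagConfig)
    bsv: BsvConfig = field(default_factory=BsvConfig)
    residual_cv: float = 0.10
    outcome: OutcomeConfig = field(default_factory=OutcomeConfig)
    seed: int = 0

    def validate(self) -> None:
        pk = self.pk
        for name, v in (("ka", pk.ka), ("cl_f_median", pk.cl_f_median),
                        ("v_f_median", pk.v_f_median),
                        ("cl_m_over_f", self.mpag.cl_m_over_f),
                        ("v_m_over_f", self.mpag.v_m_over_f)):
            if v <= 0:
                raise DomainError(f"{name} must be positive")
        if not (0.0 <= pk.ehc_fraction < 1.0):
            raise DomainError("ehc_fraction must lie in [0, 1)")
        if not (0.0 < self.outcome.target_flare_rate < 1.0):
            raise DomainError("target_flare_rate must lie in (0, 1)")
        if abs(sum(self.outcome.flare_month_weights) - 1.0) > 1e-9:
            raise DomainError("flare_month_weights must sum to 1")


def _cv_to_sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def _sep(*rates: np.ndarray) -> tuple[np.ndarray, ...]:
    """Nudge coincident exponential rates apart (analytic-limit handling).

    The closed forms below have removable singularities at equal rates;
    a relative perturbation of 1e-7 evaluates the limit to ~1e-7 accuracy.
    """
    out = [np.asarray(r, dtype=float).copy() for r in rates]
    for i in range(1, len(out)):
        for j in range(i):
            clash = np.isclose(out[i], out[j], rtol=1e-9, atol=0.0)
            out[i] = np.where(clash, out[i] * (1.0 + 1e-7), out[i])
    return tuple(out)


def _ss_exp(lam, t):
    """Periodic steady-state factor e^(-lam t) / (1 - e^(-lam tau))."""
    lam = np.asarray(lam, dtype=float)
    return np.exp(-lam * t) / (-np.expm1(-lam * TAU))


def parent_css(t, dose_mg, ka, cl, v, ehc_fraction=0.0, ehc_lag=6.0):
    """Steady-state MPA concentration (mg/L) at time(s) t within [0, tau].

    Broadcasts over patients: scalar t with array parameters, or
    ``t`` of shape (k,) with parameters of shape (n, 1).
    """
    def base(tt):
        ke = cl / v
        ka_, ke_ = _sep(ka, ke)
        coef = dose_mg * ka_ / (v * (ka_ - ke_))
        return coef * (_ss_exp(ke_, tt) - _ss_exp(ka_, tt))

    t = np.asarray(t, dtype=float)
    if ehc_fraction == 0.0:
        return base(t)
    t_lag = np.mod(t - ehc_lag, TAU)
    return (1.0 - ehc_fraction) * base(t) + ehc_fraction * base(t_lag)


def metabolite_css(t, dose_mg, ka, cl, v, fm, cl_m, v_m,
                   ehc_fraction=0.0, ehc_lag=6.0):
    """Steady-state MPAG concentration (mg/L, MPA-equivalent mass units).

    Closed-form solution of first-order formation (rate fm*CL*Cp) with
    first-order elimination km = CLm/Vm, superposed over dosing intervals.
    """
    def base(tt):
        ke = cl / v
        km = cl_m / v_m
        ka_, ke_, km_ = _sep(ka, ke, km)
        k_coef = fm * ke_ * dose_mg * ka_ / (ka_ - ke_)
        a_ke = k_coef / (km_ - ke_)
        a_ka = -k_coef / (km_ - ka_)
        a_km = k_coef * (1.0 / (km_ - ka_) - 1.0 / (km_ - ke_))
        am = (a_ke * _ss_exp(ke_, tt) + a_ka * _ss_exp(ka_, tt)
              + a_km * _ss_exp(km_, tt))
        return am / v_m

    t = np.asarray(t, dtype=float)
    if ehc_fraction == 0.0:
        return base(t)
    t_lag = np.mod(t - ehc_lag, TAU)
    return (1.0 - ehc_fraction) * base(t) + ehc_fraction * base(t_lag)


def _round_sig(x: np.ndarray, digits: int = 4) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    nz = x > 0
    mag = np.floor(np.log10(x[nz]))
    factor = 10.0 ** (digits - 1 - mag)
    out[nz] = np.round(x[nz] * factor) / factor
    return out


@dataclass
class PatientPk:
    """Individual realised PK parameters for one simulated patient."""

    dose_mg_per_interval: float
    ka: float
    cl_f: float
    v_f: float
    cl_m: float
    v_m: float
    fm: float
    ehc_fraction: float
    ehc_lag: float


def draw_pk_params(config: SimConfig, n: int, rng: np.random.Generator,
                   doses_g_day: Optional[np.ndarray] = None) -> list[PatientPk]:
    """Draw individual PK parameter sets (lognormal BSV around the medians)."""
    bsv = config.bsv
    pk = config.pk
    if doses_g_day is None:
        doses_g_day = np.full(n, config.dose_g_day)
    cl = pk.cl_f_median * np.exp(rng.normal(0, _cv_to_sigma(bsv.cl), n))
    v = pk.v_f_median * np.exp(rng.normal(0, _cv_to_sigma(bsv.v), n))
    ka = pk.ka * np.exp(rng.normal(0, _cv_to_sigma(bsv.ka), n))
    cl_m = config.mpag.cl_m_over_f * np.exp(rng.normal(0, _cv_to_sigma(bsv.cl_m), n))
    v_m = config.mpag.v_m_over_f * (cl_m / config.mpag.cl_m_over_f)  # km preserved
    return [PatientPk(float(doses_g_day[i]) / 2.0 * 1000.0, float(ka[i]),
                      float(cl[i]), float(v[i]), float(cl_m[i]), float(v_m[i]),
                      config.mpag.fm, pk.ehc_fraction, pk.ehc_lag)
            for i in range(n)]


def true_trough(params: PatientPk) -> float:
    """Noise-free model C12h (mg/L) for one parameter set."""
    return float(parent_css(TAU, params.dose_mg_per_interval, params.ka,
                            params.cl_f, params.v_f, params.ehc_fraction,
                            params.ehc_lag))


def simulate_pk_profile(params: PatientPk, rng: np.random.Generator,
                        schedule: Sequence[float] = STANDARD_SCHEDULE,
                        residual_cv: float = 0.10,
                        patient_id: str = "sim",
                        ) -> tuple[ConcProfile, ConcProfile]:
    """Sample one patient's MPA and MPAG profiles on the blood schedule.

    Multiplicative lognormal residual error per sample; concentrations
    rounded to 4 significant digits and floored at 0. Identical rng state
    and params give bitwise-identical profiles.
    """
    t = np.asarray(schedule, dtype=float)
    mpa = parent_css(t, params.dose_mg_per_interval, params.ka, params.cl_f,
                     params.v_f, params.ehc_fraction, params.ehc_lag)
    mpag = metabolite_css(t, params.dose_mg_per_interval, params.ka,
                          params.cl_f, params.v_f, params.fm, params.cl_m,
                          params.v_m, params.ehc_fraction, params.ehc_lag)
    if residual_cv > 0:
        sig = _cv_to_sigma(residual_cv)
        mpa = mpa * np.exp(rng.normal(0, sig, t.size))
        mpag = mpag * np.exp(rng.normal(0, sig, t.size))
    mpa = _round_sig(np.maximum(mpa, 0.0))
    mpag = _round_sig(np.maximum(mpag, 0.0))
    return (ConcProfile(patient_id, "MPA", t.copy(), mpa),
            ConcProfile(patient_id, "MPAG", t.copy(), mpag))


def _trough_sample(config: SimConfig, n: int, rng: np.random.Generator
                   ) -> np.ndarray:
    """Vectorised noise-free trough draw (same distribution as the cohort)."""
    bsv, pk = config.bsv, config.pk
    doses = rng.choice(np.asarray(config.dose_choices), size=n,
                       p=np.asarray(config.dose_probs))
    cl = pk.cl_f_median * np.exp(rng.normal(0, _cv_to_sigma(bsv.cl), n))
    v = pk.v_f_median * np.exp(rng.normal(0, _cv_to_sigma(bsv.v), n))
    ka = pk.ka * np.exp(rng.normal(0, _cv_to_sigma(bsv.ka), n))
    return parent_css(TAU, doses / 2.0 * 1000.0, ka, cl, v,
                      pk.ehc_fraction, pk.ehc_lag)


def calibrate_intercept(config: SimConfig, n_calib: int = 100_000,
                        tol: float = 1e-4) -> float:
    """Intercept beta0 giving the target population flare rate.

    With ``beta1 = 0`` the closed form ``logit(target)`` is returned.
    Otherwise the expected flare rate E[expit(beta0 + beta1 ln C12h)] is
    evaluated on a large noise-free trough sample (drawn from a dedicated
    stream of the config seed, so the result is deterministic) and beta0 is
    solved by root-finding to within ``tol``.
    """
    config.validate()
    oc = config.outcome
    if oc.beta1 == 0.0:
        return float(logit(oc.target_flare_rate))
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xCA11B]))
    c12 = _trough_sample(config, n_calib, rng)
    if np.all(c12 <= 0):
        raise CalibrationError("degenerate trough distribution (no positive troughs)")
    x = oc.beta1 * np.log(np.maximum(c12, 1e-12))

    def rate(beta0: float) -> float:
        return float(np.mean(expit(beta0 + x))) - oc.target_flare_rate

    lo, hi = -50.0, 50.0
    if rate(lo) > 0 or rate(hi) < 0:
        raise CalibrationError("target flare rate unattainable for this trough distribution")
    return float(brentq(rate, lo, hi, xtol=tol))


def expected_flare_rate(config: SimConfig, beta0: float,
                        c12h: np.ndarray) -> float:
    """Mean flare probability of a population of troughs under the model."""
    x = config.outcome.beta1 * np.log(np.maximum(c12h, 1e-12))
    return float(np.mean(expit(beta0 + x)))


def assign_outcomes(c12h_values: np.ndarray, outcome: OutcomeConfig,
                    rng: np.random.Generator, beta0: float,
                    sledai_entry: Optional[np.ndarray] = None,
                    ) -> tuple[np.ndarray, np.ndarray, list[list[int]]]:
    """Draw flare labels, flare months and SLEDAI trajectories.

    Returns (flare: bool[n], flare_month: int[n] with -1 for none,
    trajectories: per-patient SLEDAI at months 0..6). Trajectories encode
    the label exactly: failures jump by 3-6 points at the flare month,
    successes never move by more than 1 point between visits.
    """
    c12 = np.asarray(c12h_values, dtype=float)
    if np.any(c12 <= 0):
        raise DomainError("troughs must be positive to evaluate the outcome model")
    n = c12.size
    p = expit(beta0 + outcome.beta1 * np.log(c12))
    flare = rng.random(n) < p
    months = np.full(n, -1, dtype=int)
    k = int(flare.sum())
    months[flare] = rng.choice(np.arange(1, 7), size=k,
                               p=np.asarray(outcome.flare_month_weights))
    if sledai_entry is None:
        sledai_entry = np.zeros(n, dtype=int)
    trajectories: list[list[int]] = []
    for i in range(n):
        s = int(sledai_entry[i])
        traj = [s]
        for m in range(1, 7):
            if flare[i] and m == months[i]:
                s = s + int(rng.integers(3, 7))
            elif not flare[i]:
                s = max(0, s + int(rng.integers(-1, 2)))
            # failures hold their score before and after the flare
            traj.append(s)
        trajectories.append(traj)
    return flare, months, trajectories


def _draw_patients(config: SimConfig, rng: np.random.Generator
                   ) -> list[PatientRecord]:
    n = config.n_patients
    patients = []
    doses = rng.choice(np.asarray(config.dose_choices), size=n,
                       p=np.asarray(config.dose_probs))
    for i in range(n):
        pid = f"P{i + 1:03d}"
        sex = "female" if rng.random() < 16 / 26 else "male"
        age = float(np.clip(rng.normal(47, 13), 20, 78))
        weight = float(62.0 * np.exp(rng.normal(0, 0.16)))
        # reject creatinine draws that fail the renal screen: the simulated
        # cohort represents patients who passed eligibility
        for _ in range(100):
            scr = float(0.72 * np.exp(rng.normal(0, 0.18)))
            gfr = cockcroft_gault(age, weight, scr, sex)
            if gfr >= 60:
                break
        maintenance = rng.random() < 0.6
        pred = (float(rng.uniform(5, 10)) if maintenance
                else float(rng.uniform(15, 45)))
        patients.append(PatientRecord(
            patient_id=pid, sex=sex, age=age, weight=weight,
            serum_creatinine=scr,
            albumin=float(rng.normal(41, 3)),
            c3=float(0.95 * np.exp(rng.normal(0, 0.25))),
            c4=float(0.19 * np.exp(rng.normal(0, 0.30))),
            anti_dsdna=float(20.0 * np.exp(rng.normal(0, 1.0))),
            gfr=gfr,
            mmf_dose=float(doses[i]),
            prednisone_dose=round(pred, 1),
            months_on_mmf=float(rng.choice([1, 2, 3, 4, 5, 6],
                                           p=[0.3, 0.3, 0.2, 0.1, 0.06, 0.04])),
            months_on_steroids=float(np.clip(round(rng.normal(10, 5)), 1, 30)),
            sledai_entry=int(rng.choice([0, 1, 2, 3, 4],
                                        p=[0.55, 0.15, 0.15, 0.10, 0.05])),
        ))
    return patients


def _prednisone_course(dose0: float) -> list[float]:
    """Monthly prednisone under the protocol taper.

    Induction-range doses (> 10 mg/day) taper by 5 mg per 15 days
    (10 mg/month); maintenance doses taper by 1 mg per 15 days
    (2 mg/month); both floor at 0.
    """
    rate = 10.0 if dose0 > 10.0 else 2.0
    return [max(0.0, dose0 - rate * m) for m in range(7)]


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate a complete validation-passing cohort with outcomes.

    Stream order (documented contract): patients -> profiles -> outcomes,
    all derived from the single master seed.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_patients, rng_profiles, rng_outcomes = map(np.random.default_rng,
                                                   ss.spawn(3))
    patients = _draw_patients(config, rng_patients)
    doses = np.array([p.mmf_dose for p in patients])
    pk_sets = draw_pk_params(config, len(patients), rng_profiles, doses)
    profiles = []
    for patient, pkp in zip(patients, pk_sets):
        mpa, mpag = simulate_pk_profile(pkp, rng_profiles,
                                        residual_cv=config.residual_cv,
                                        patient_id=patient.patient_id)
        profiles.extend([mpa, mpag])

    beta0 = config.outcome.beta0
    if beta0 is None:
        beta0 = calibrate_intercept(config)
    c12_true = np.array([true_trough(p) for p in pk_sets])
    sledai_entry = np.array([p.sledai_entry for p in patients])
    flare, months, trajectories = assign_outcomes(
        c12_true, config.outcome, rng_outcomes, beta0, sledai_entry)

    visits: list[VisitRecord] = []
    outcomes: list[OutcomeLabel] = []
    for i, patient in enumerate(patients):
        course = _prednisone_course(patient.prednisone_dose)
        for m in range(7):
            visits.append(VisitRecord(patient.patient_id, m,
                                      trajectories[i][m], course[m]))
        if rng_outcomes.random() < config.outcome.discontinuation_rate:
            outcomes.append(OutcomeLabel(patient.patient_id, "excluded",
                                         exclusion_reason="treatment_discontinuation"))
        elif flare[i]:
            outcomes.append(OutcomeLabel(patient.patient_id, "failure",
                                         flare_month=int(months[i])))
        else:
            outcomes.append(OutcomeLabel(patient.patient_id, "success"))
    return Cohort(patients, profiles, visits, outcomes).validate()


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of the config with a different master seed."""
    return replace(config, seed=seed)
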