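"""On-disk cohort model: four CSV tables, read/validate/write, report rendering.

Dialect: comma separator, UTF-8, "." decimal, mandatory header row. Missing
numeric cells are written as empty strings and surfaced as ``None`` (absent),
never as zero — zero is a legal concentration. Floats are written at 12
significant digits so that read(write(cohort)) round-trips bit-stably for
testing purposes.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .model import Cohort, ConcProfile, OutcomeLabel, PatientRecord, VisitRecord

PATIENT_COLUMNS = [
    "patient_id", "sex", "age_years", "weight_kg", "serum_creatinine_mg_dl",
    "albumin_g_l", "c3_g_l", "c4_g_l", "anti_dsdna_iu_ml", "gfr_ml_min",
    "mmf_dose_g_day", "prednisone_mg_day", "months_on_mmf", "months_on_steroids",
    "sledai_entry", "proteinuria_over_0_5g", "hepatic_dysfunction",
    "forbidden_comedication",
]
SAMPLE_COLUMNS = ["patient_id", "analyte", "time_h", "concentration_mg_l"]
VISIT_COLUMNS = ["patient_id", "month", "sledai", "prednisone_mg_day"]
OUTCOME_COLUMNS = ["patient_id", "label", "flare_month", "exclusion_reason"]

#: conversion factor between serum creatinine in umol/L and mg/dL
UMOL_PER_MG_DL = 88.4


def _read_table(path: str, required: list[str], name: str,
                optional_numeric_alias: Optional[dict[str, str]] = None) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in required if c not in df.columns]
    if optional_numeric_alias:
        # a column may be satisfied by its accepted alias (unit variant)
        missing = [c for c in missing if optional_numeric_alias.get(c) not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing required column(s) {missing} in {path}")
    return df


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return float(value)


def _opt_int(value) -> Optional[int]:
    v = _opt_float(value)
    return None if v is None else int(v)


def _req_float(value, pid: str, column: str) -> float:
    v = _opt_float(value)
    if v is None:
        raise ValidationError(f"{pid}: required numeric cell '{column}' is empty")
    return v


def _as_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in ("true", "1", "yes")
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return False
    return bool(value)


def read_cohort(patients_path: str, samples_path: str, visits_path: str,
                outcomes_path: Optional[str] = None,
                require_profiles: bool = True) -> Cohort:
    """Read and validate the four cohort tables.

    ``outcomes_path`` may be ``None`` (or a non-existent path) for cohorts
    whose outcomes have not yet been assigned. Unknown columns are ignored.
    A ``serum_creatinine_umol_l`` column is accepted in place of
    ``serum_creatinine_mg_dl`` and converted by dividing by 88.4.
    """
    pdf = _read_table(
        patients_path, PATIENT_COLUMNS, "patients.csv",
        optional_numeric_alias={"serum_creatinine_mg_dl": "serum_creatinine_umol_l"})
    sdf = _read_table(samples_path, SAMPLE_COLUMNS, "samples.csv")
    vdf = _read_table(visits_path, VISIT_COLUMNS, "visits.csv")

    patients = []
    for _, row in pdf.iterrows():
        pid = str(row["patient_id"])
        if "serum_creatinine_mg_dl" in pdf.columns and _opt_float(row.get("serum_creatinine_mg_dl")) is not None:
            scr = _req_float(row["serum_creatinine_mg_dl"], pid, "serum_creatinine_mg_dl")
        else:
            scr = _req_float(row["serum_creatinine_umol_l"], pid,
                             "serum_creatinine_umol_l") / UMOL_PER_MG_DL
        patients.append(PatientRecord(
            patient_id=pid,
            sex=str(row["sex"]).strip().lower(),
            age=_req_float(row["age_years"], pid, "age_years"),
            weight=_req_float(row["weight_kg"], pid, "weight_kg"),
            serum_creatinine=scr,
            albumin=_opt_float(row["albumin_g_l"]),
            c3=_opt_float(row["c3_g_l"]),
            c4=_opt_float(row["c4_g_l"]),
            anti_dsdna=_opt_float(row["anti_dsdna_iu_ml"]),
            gfr=_opt_float(row["gfr_ml_min"]),
            mmf_dose=_req_float(row["mmf_dose_g_day"], pid, "mmf_dose_g_day"),
            prednisone_dose=_req_float(row["prednisone_mg_day"], pid, "prednisone_mg_day"),
            months_on_mmf=_opt_float(row["months_on_mmf"]),
            months_on_steroids=_opt_float(row["months_on_steroids"]),
            sledai_entry=int(_req_float(row["sledai_entry"], pid, "sledai_entry")),
            proteinuria_over_0_5g=_as_bool(row["proteinuria_over_0_5g"]),
            hepatic_dysfunction=_as_bool(row["hepatic_dysfunction"]),
            forbidden_comedication=_as_bool(row["forbidden_comedication"]),
        ))

    profiles = []
    if len(sdf):
        for (pid, analyte), grp in sdf.groupby(["patient_id", "analyte"], sort=True):
            for i, row in grp.iterrows():
                c = _opt_float(row["concentration_mg_l"])
                if c is not None and c < 0:
                    raise ValidationError(
                        f"{pid}/{analyte}: negative concentration "
                        f"{c} at t={row['time_h']} h (samples.csv row {i + 2})")
            grp = grp.dropna(subset=["concentration_mg_l"]).sort_values("time_h")
            profiles.append(ConcProfile(
                patient_id=str(pid), analyte=str(analyte),
                times=grp["time_h"].to_numpy(float),
                concentrations=grp["concentration_mg_l"].to_numpy(float)))

    visits = [VisitRecord(patient_id=str(r["patient_id"]), month=int(r["month"]),
                          sledai=int(r["sledai"]),
                          prednisone_dose=_req_float(r["prednisone_mg_day"],
                                                     str(r["patient_id"]),
                                                     "prednisone_mg_day"))
              for _, r in vdf.iterrows()]

    outcomes = None
    if outcomes_path is not None and os.path.exists(outcomes_path):
        odf = _read_table(outcomes_path, OUTCOME_COLUMNS, "outcomes.csv")
        outcomes = [OutcomeLabel(
            patient_id=str(r["patient_id"]), label=str(r["label"]).strip(),
            flare_month=_opt_int(r["flare_month"]),
            exclusion_reason=(None if _is_blank(r["exclusion_reason"])
                              else str(r["exclusion_reason"])))
            for _, r in odf.iterrows()]

    return Cohort(patients, profiles, visits, outcomes).validate(
        require_profiles=require_profiles)


def _is_blank(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v)) or v == ""


def _fmt(v) -> str:
    """Format a float at 12 significant digits; empty string for absent."""
    if v is None:
        return ""
    if isinstance(v, bool):
        return str(v)
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    return f"{v:.12g}"


def write_cohort(cohort: Cohort, directory: str) -> dict[str, str]:
    """Write the cohort tables under ``directory``; returns table -> path.

    ``outcomes.csv`` is written only when the cohort carries outcomes.
    """
    cohort.validate(require_profiles=False)
    os.makedirs(directory, exist_ok=True)
    paths = {}

    rows = []
    for p in cohort.patients:
        rows.append([p.patient_id, p.sex, _fmt(p.age), _fmt(p.weight),
                     _fmt(p.serum_creatinine), _fmt(p.albumin), _fmt(p.c3),
                     _fmt(p.c4), _fmt(p.anti_dsdna), _fmt(p.gfr),
                     _fmt(p.mmf_dose), _fmt(p.prednisone_dose),
                     _fmt(p.months_on_mmf), _fmt(p.months_on_steroids),
                     str(p.sledai_entry), str(p.proteinuria_over_0_5g),
                     str(p.hepatic_dysfunction), str(p.forbidden_comedication)])
    paths["patients"] = _write(directory, "patients.csv", PATIENT_COLUMNS, rows)

    rows = []
    for prof in cohort.profiles:
        for t, c in zip(prof.times, prof.concentrations):
            rows.append([prof.patient_id, prof.analyte, _fmt(float(t)), _fmt(float(c))])
    paths["samples"] = _write(directory, "samples.csv", SAMPLE_COLUMNS, rows)

    rows = [[v.patient_id, str(v.month), str(v.sledai), _fmt(v.prednisone_dose)]
            for v in cohort.visits]
    paths["visits"] = _write(directory, "visits.csv", VISIT_COLUMNS, rows)

    if cohort.outcomes is not None:
        rows = [[o.patient_id, o.label,
                 "" if o.flare_month is None else str(o.flare_month),
                 o.exclusion_reason or ""] for o in cohort.outcomes]
        paths["outcomes"] = _write(directory, "outcomes.csv", OUTCOME_COLUMNS, rows)
    return paths


def _write(directory: str, name: str, header: list[str],
           rows: Iterable[list[str]]) -> str:
    path = os.path.join(directory, name)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(header) + "\n")
        for row in rows:
            fh.write(",".join(row) + "\n")
    return path


def render_comparison_report(group_summary, path: str) -> str:
    """Render a success-vs-failure comparison as a publication-style table.

    ``group_summary`` is the list produced by
    :func:`mpa_tdm.stats.compare_groups`, already in canonical row order.
    Cells are "median (Q1-Q3)" strings; groups with no data render "NA".
    """
    def cell(median, q1, q3):
        if median is None:
            return "NA"
        return f"{median:g} ({q1:g}-{q3:g})"

    lines = ["characteristic,total,successes,failures,p_value"]
    for g in group_summary:
        if g.test == "fisher_exact":
            total = g.total_counts or "NA"
            succ = g.success_counts or "NA"
            fail = g.failure_counts or "NA"
        else:
            total = cell(g.total_median, g.total_q1, g.total_q3)
            succ = cell(g.success_median, g.success_q1, g.success_q3)
            fail = cell(g.failure_median, g.failure_q1, g.failure_q3)
        p = "NA" if g.p_value is None else f"{g.p_value:.4g}"
        lines.append(f"{g.characteristic},{total},{succ},{fail},{p}")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
    return path
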