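"""Flare-based outcome classification.

Re-derives success / failure / excluded labels from the monthly SLEDAI
trajectories (a flare is a >= 3-point rise between consecutive visits;
treatment discontinuation excludes a patient from the PK-PD analysis) and
writes results/outcomes.csv.
"""

import pathlib

import pandas as pd

from mpa_tdm.eligibility import classify_outcomes
from mpa_tdm.io import read_cohort

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main():
    d = ROOT / "cohort"
    cohort = read_cohort(d / "patients.csv", d / "samples.csv",
                         d / "visits.csv", d / "outcomes.csv")
    discontinued = [o.patient_id for o in (cohort.outcomes or [])
                    if o.label == "excluded"]
    labels = classify_outcomes(cohort, discontinued)
    df = pd.DataFrame([{"patient_id": o.patient_id, "label": o.label,
                        "flare_month": o.flare_month,
                        "exclusion_reason": o.exclusion_reason}
                       for o in labels])
    out = ROOT / "outcomes.csv"
    df.to_csv(out, index=False)
    counts = df.label.value_counts()
    print(f"enrolled {len(df)}, analyzed {int((df.label != 'excluded').sum())}: "
          + ", ".join(f"{k}={v}" for k, v in counts.items()))
    flares = df.dropna(subset=["flare_month"]).flare_month.astype(int)
    if len(flares):
        print(f"flare months: {sorted(flares.tolist())} "
              f"(median {flares.median():.0f})")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
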