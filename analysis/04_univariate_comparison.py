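"""Univariate success-vs-failure comparison and exposure correlations.

Compares every inclusion characteristic and PK metric between successes
and failures (Mann-Whitney for continuous rows, Fisher exact for sex) and
computes the standard Spearman correlation pairs. Writes
results/comparison.csv and results/correlations.csv.
"""

import pathlib

import pandas as pd

from mpa_tdm.io import read_cohort, render_comparison_report
from mpa_tdm.stats import (compare_groups, correlation_frame, correlations)

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main():
    d = ROOT / "cohort"
    cohort = read_cohort(d / "patients.csv", d / "samples.csv",
                         d / "visits.csv", d / "outcomes.csv")
    pk = pd.read_csv(ROOT / "pk_params.csv", dtype={"patient_id": str})
    outcomes_df = pd.read_csv(ROOT / "outcomes.csv", dtype={"patient_id": str})

    class Label:
        def __init__(self, pid, label):
            self.patient_id, self.label = pid, label

    labels = [Label(r.patient_id, r.label) for r in outcomes_df.itertuples()]
    rows = compare_groups(cohort, pk, labels)
    path = render_comparison_report(rows, str(ROOT / "comparison.csv"))
    print(f"wrote {path}")
    for g in rows:
        if g.p_value is not None and g.p_value < 0.05:
            print(f"  {g.characteristic}: P = {g.p_value:.3f} "
                  f"(successes {g.success_median} vs failures {g.failure_median})"
                  if g.test == "mann_whitney" else
                  f"  {g.characteristic}: P = {g.p_value:.3f}")
    corr = correlation_frame(correlations(cohort, pk, labels))
    cpath = ROOT / "correlations.csv"
    corr.to_csv(cpath, index=False, float_format="%.6g")
    print(f"wrote {cpath}")


if __name__ == "__main__":
    main()
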