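"""Non-compartmental exposure metrics for the simulated cohort.

Reads results/cohort/, computes AUC_0-12h (linear-up/log-down), Cmax,
Tmax, C12h for MPA and MPAG plus the MPAG/MPA ratios, writes
results/pk_params.csv and prints the cohort medians (IQR).
"""

import pathlib

from mpa_tdm.io import read_cohort
from mpa_tdm.nca import pk_params_frame, pk_summary
from mpa_tdm.stats import median_iqr

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main():
    d = ROOT / "cohort"
    cohort = read_cohort(d / "patients.csv", d / "samples.csv",
                         d / "visits.csv", d / "outcomes.csv")
    frame = pk_params_frame(pk_summary(cohort))
    out = ROOT / "pk_params.csv"
    frame.to_csv(out, index=False, float_format="%.12g")
    print(f"wrote {len(frame)} rows to {out}")
    for col in ("mpa_auc_0_12", "mpa_cmax", "mpa_tmax", "mpa_c12h",
                "mpag_auc_0_12", "mpag_c12h", "ratio_auc", "ratio_c12h"):
        med, q1, q3 = median_iqr(frame[col].dropna())
        print(f"  {col}: {med:.2f} ({q1:.2f}-{q3:.2f})")


if __name__ == "__main__":
    main()
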