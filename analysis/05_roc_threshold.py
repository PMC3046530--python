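"""ROC analysis and trough-threshold derivation.

Builds empirical ROC curves for MPA AUC_0-12h, MPA C12h (low exposure
predicts a flare) and the MPAG/MPA C12h ratio (high ratio predicts a
flare), attaches Hanley-McNeil 95% CIs, compares the paired AUC of the two
MPA metrics with the DeLong test, and reports the Youden-optimal cutoff
with its predictive values. Writes results/roc_results.csv and
results/thresholds.csv.
"""

import pathlib

import pandas as pd

from mpa_tdm.roc import (HIGHER, LOWER, auc, compare_paired_auc,
                         empirical_roc, hanley_mcneil, metrics_at,
                         optimal_threshold)

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"
PREDICTORS = [("mpa_auc_0_12", LOWER), ("mpa_c12h", LOWER),
              ("ratio_c12h", HIGHER)]


def main():
    pk = pd.read_csv(ROOT / "pk_params.csv", dtype={"patient_id": str})
    outcomes = pd.read_csv(ROOT / "outcomes.csv", dtype={"patient_id": str})
    merged = outcomes[outcomes.label.isin(["success", "failure"])].merge(
        pk, on="patient_id")
    y = (merged.label == "failure").astype(int).to_numpy()

    roc_rows, thr_rows = [], []
    for predictor, direction in PREDICTORS:
        scores = merged[predictor].to_numpy(float)
        curve = empirical_roc(scores, y, direction, predictor)
        res = hanley_mcneil(auc(curve), curve.n_pos, curve.n_neg)
        roc_rows.append(dict(predictor=predictor, direction=direction,
                             auc=res.auc, se=res.se, ci_low=res.ci_low,
                             ci_high=res.ci_high))
        m = optimal_threshold(scores, y, direction)
        thr_rows.append(dict(predictor=predictor, cutoff=m.cutoff,
                             sensitivity=m.sensitivity, specificity=m.specificity,
                             ppv=m.ppv, npv=m.npv, youden_j=m.youden_j,
                             tp=m.tp, fp=m.fp, tn=m.tn, fn=m.fn))
        print(f"{predictor}: AUC {res.auc:.2f} "
              f"(95% CI {res.ci_low:.2f}-{res.ci_high:.2f}); "
              f"Youden cutoff {m.cutoff:g} -> sens {m.sensitivity:.0%}, "
              f"spec {m.specificity:.0%}, NPV "
              f"{'NA' if m.npv is None else format(m.npv, '.0%')}")

    delta, z, p = compare_paired_auc(merged.mpa_c12h, merged.mpa_auc_0_12, y,
                                     LOWER, LOWER)
    print(f"paired AUC, C12h vs AUC_0-12h: delta {delta:+.3f}, P = {p:.2f}")
    at3 = metrics_at(merged.mpa_c12h.to_numpy(float), y, 3.0, LOWER)
    print(f"fixed 3 mg/L trough cutoff: sens {at3.sensitivity:.0%}, "
          f"spec {at3.specificity:.0%}, NPV "
          f"{'NA' if at3.npv is None else format(at3.npv, '.0%')}")

    pd.DataFrame(roc_rows).to_csv(ROOT / "roc_results.csv", index=False,
                                  float_format="%.6g")
    pd.DataFrame(thr_rows).to_csv(ROOT / "thresholds.csv", index=False,
                                  float_format="%.6g")
    print(f"wrote {ROOT / 'roc_results.csv'} and {ROOT / 'thresholds.csv'}")


if __name__ == "__main__":
    main()
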