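# mpa-tdm

Steady-state mycophenolic acid (MPA) exposure metrics as predictors of
systemic lupus erythematosus (SLE) flares under mycophenolate mofetil (MMF)
maintenance therapy — a reusable pharmacokinetic-pharmacodynamic (PK-PD)
analysis pipeline with a calibrated synthetic-cohort simulator.

## Who this is for

Clinical pharmacologists and biostatisticians working on therapeutic drug
monitoring (TDM) of MMF in autoimmune disease. The package turns a small
observational cohort — 9-point MPA/MPAG concentration-time profiles at
inclusion, monthly SLEDAI follow-up — into the standard TDM questions: do
flaring patients have lower exposure, which exposure metric discriminates
best, and what trough concentration should be the efficacy target?

## What it computes

- **Non-compartmental analysis (NCA).** For each patient and analyte (MPA
  and its glucuronide MPAG), AUC₀₋₁₂ₕ by the linear-up/log-down trapezoidal
  rule, Cmax, Tmax and the observed 12-hour trough C₁₂ₕ, plus the MPAG/MPA
  AUC and trough ratios. At steady state AUC₀₋₁₂ₕ = D/(CL/F), which the test
  suite uses as a closed-form oracle.
- **Outcomes.** A flare is a rise of ≥ 3 SLEDAI points between consecutive
  monthly visits; patients flare-free over 6 months are successes, patients
  who discontinue therapy are excluded from the PK-PD analysis. Eligibility
  screening includes the Cockcroft-Gault creatinine clearance
  `CrCl = (140 − age)·weight / (72·SCr) · (0.85 if female)`.
- **Univariate statistics.** Median (Q1-Q3) summaries, two-sided
  Mann-Whitney U (exact for pooled n ≤ 20 without ties), Fisher exact
  (point-probability rule), Spearman correlations (exact permutation for
  n ≤ 9). No multiplicity adjustment — it is a univariate screen.
- **ROC and threshold.** Empirical ROC per predictor with an explicit
  orientation (low exposure ⇒ flare; high MPAG/MPA ratio ⇒ flare), AUC with
  the Hanley-McNeil standard error
  `SE² = [A(1−A) + (n₁−1)(Q₁−A²) + (n₀−1)(Q₂−A²)]/(n₁n₀)`,
  Q₁ = A/(2−A), Q₂ = 2A²/(1+A), 95% CI truncated to [0, 1]; DeLong paired
  AUC comparison; Youden-optimal cutoff (J = sens + spec − 1) with
  sensitivity, specificity, PPV and NPV.
- **Simulator.** A one-compartment steady-state model with first-order
  absorption, an enterohepatic-recirculation dose split, a closed-form
  metabolite solution, lognormal between-patient variability, and a
  logistic flare model on ln C₁₂ₕ calibrated to a 31% six-month flare rate.
  See `docs/methods.md`.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_exposure_nca.py
python analysis/03_outcomes.py
python analysis/04_univariate_comparison.py
python analysis/05_roc_threshold.py
```

The drivers write their tables under `results/`. With the default seed (7)
the 26-patient cohort gives:

```
mpa_auc_0_12: 69.76 (41.58-93.43)      # mg·h/L, median (IQR)
mpa_c12h: 3.04 (1.72-4.96)             # mg/L
ratio_auc: 10.99 (5.73-16.47)          # MPAG/MPA
enrolled 26, analyzed 26: success=19, failure=7
mpa_c12h: P = 0.015 (successes 3.83 vs failures 0.92)
mpa_c12h: AUC 0.82 (95% CI 0.61-1.00); Youden cutoff 2.483 -> sens 86%, spec 68%, NPV 93%
paired AUC, C12h vs AUC_0-12h: delta +0.023, P = 0.58
fixed 3 mg/L trough cutoff: sens 86%, spec 63%, NPV 92%
```

Read: flaring patients had markedly lower troughs (0.92 vs 3.83 mg/L,
Mann-Whitney P = 0.015); the trough discriminates flares about as well as
the full AUC (DeLong P = 0.58), and a patient with C₁₂ₕ ≥ 3 mg/L has a 92%
probability of staying flare-free over the next 6 months in this cohort.

The same pipeline runs one-shot from the console:

```bash
mpa-tdm simulate --n 26 --seed 7 --out cohort/
mpa-tdm nca --cohort cohort/ --method linlog --out pk_params.csv
mpa-tdm analyze --simulate-n 26 --seed 7 --out run/
mpa-tdm roc --pk pk_params.csv --outcomes cohort/outcomes.csv \
            --predictor mpa_c12h --direction lower-positive
```

or from disk data: put `patients.csv`, `samples.csv`, `visits.csv` (and
optionally `outcomes.csv`) in a directory and pass `--cohort DIR` to
`mpa-tdm analyze`. Column schemas are documented in `mpa_tdm/io.py`.

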