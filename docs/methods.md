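# Methods

## Scope and model of the data

The package analyzes an SLE maintenance-therapy cohort in which every
patient contributes, at inclusion, a steady-state concentration-time
profile of MPA and MPAG sampled pre-dose and 0.5, 1, 2, 3, 4, 6, 8 and 12
hours after the morning MMF dose, plus monthly SLEDAI and prednisone
records over six months of follow-up. Exposure metrics are estimated
non-compartmentally, outcomes are derived from the SLEDAI trajectory, and
the exposure-outcome link is assessed by univariate tests, ROC analysis
and threshold derivation. No patient-level data ship with the package; a
simulator generates cohorts with the assumed statistical structure.

## Non-compartmental analysis

AUC₀₋₁₂ₕ sums per-segment trapezoids. The "logarithmic trapezoidal" rule
is implemented as the field-standard linear-up/log-down hybrid: on a
segment with c₁ > c₂ > 0 the exponential interpolant gives
(t₂−t₁)(c₁−c₂)/ln(c₁/c₂); ascending, flat or zero-bounded segments use the
linear trapezoid, where the log form is undefined. A pure log-trapezoid
rule cannot integrate ascending or equal segments, so the hybrid is a
deliberate reading, and a pure-linear mode is retained for sensitivity
analysis (the linear chord always dominates the convex exponential on
descending segments, a property the tests assert).

C₁₂ₕ is the observed 12-hour sample — never extrapolated. Tmax ties break
to the earliest time. Absent concentration cells are dropped (the segment
spans the gap); a concentration of exactly 0 is legal and handled by the
linear branch. Strict mode requires the t = 0 and t = 12 samples (±0.01 h)
and at least 7 points; sparser profiles integrate only with
`strict=False`. No terminal-slope, half-life or clearance estimation is
attempted, since the 12-hour interval at steady state already fixes
AUC = D/(CL/F). Patients failing NCA preconditions are reported with a
diagnostic note and NaN metrics, never silently dropped.

## Eligibility and outcomes

Renal screening uses the raw Cockcroft-Gault output compared with
60 mL/min. The 1.73 m² body-surface normalization sometimes attached to
GFR thresholds is *not* applied: Cockcroft-Gault estimates creatinine
clearance, not a BSA-indexed GFR, and no reconciliation rule exists; this
is a documented package choice. A flare is the earliest month with a
SLEDAI rise ≥ 3 versus the *previous* visit (translation-invariant by
construction); decreases of any size are successes. Follow-up after the
first qualifying month is not re-scanned — the primary outcome is
time-to-first-flare. Treatment discontinuation excludes a patient and
takes precedence over any flare, because excluded patients never enter the
PK-PD analysis; pipelines report both enrolled and analyzed denominators.

## Statistics

Quantiles use linear interpolation between order statistics (recorded in
run metadata; other conventions shift small-sample IQRs). Mann-Whitney is
exact by enumeration for pooled n ≤ 20 without ties, otherwise a normal
approximation with tie and continuity corrections; the two agree within
0.02 for tie-free 10-vs-10 samples (asserted). Fisher's exact two-sided p
uses the point-probability rule (sum of tables no more probable than the
observed one); the doubled-one-sided rule is available as an option.
Spearman p is by exact permutation for n ≤ 9, else the t approximation.
All tests are two-sided. No multiple-testing correction is applied — the
comparison table is a univariate screen and reports should footnote that.

## ROC analysis

Predictor orientation is explicit: for exposure metrics the positive class
(flare) is called at *low* values (`lower_is_positive`, test-positive when
score < cutoff), for the MPAG/MPA ratio at high values. The empirical AUC
equals the tie-adjusted pairwise concordance exactly (asserted to 1e-12
against an O(n²) oracle and sklearn).

The Hanley-McNeil SE uses the Q1/Q2 closed forms with a normal CI
truncated to [0, 1]. Those approximations derive from an exponential score
model: for binormal scores at the study's group sizes (8 positives, 17
negatives) the SE tracks the Monte-Carlo sampling SE within ~15% up to
A ≈ 0.85 and becomes progressively conservative above (about +16% at
A = 0.9 and +25% at A = 0.95, never anti-conservative). Users should read
high-discrimination CIs as slightly wide.

Paired predictors are compared with the DeLong placement-value
construction rather than the correlation-table approach, because DeLong is
fully specified, table-free and exact under ties; rank-equivalent
predictors give Δ = 0, p = 1 identically.

The recommended cutoff maximizes the Youden index over all observed
cutpoints (plus one sentinel so the all-positive call is reachable); ties
break toward higher NPV, then higher specificity — NPV is the clinically
load-bearing quantity for a "safe exposure" threshold. An empirical ROC on
8 positives can only attain sensitivities k/8, so reported
sensitivity/specificity pairs are strongly quantized at study scale;
smoothed-ROC figures from other software are not reproducible by this
estimator and no smoothing is attempted.

## Simulator

**PK.** One-compartment, first-order absorption, periodic steady state
over τ = 12 h (every exponential e^(−λt) carries the accumulation factor
1/(1−e^(−λτ))). Enterohepatic recirculation is modelled by *splitting* the
absorbed dose — fraction f re-absorbed after a lag (default 0.15 at 6 h) —
which produces the characteristic secondary bump while preserving
AUC_ss = D/(CL/F) exactly; an additive re-dose would inflate exposure by
(1+f) and break that identity. MPAG follows the closed-form first-order
metabolite solution with formation fraction fm = 0.95 and its own
clearance/volume. Coincident rate constants (ka = ke, etc.) are evaluated
by a 1e-7 relative rate perturbation, accurate to ~1e-7 — the analytic
limit without special-cased algebra.

Defaults are calibrated to the cohort summaries the analysis targets:
CL/F = 15.4 L/h gives a median MPA AUC₀₋₁₂ₕ of 64.9 mg·h/L at 2 g/day;
V/F = 90 L (ke ≈ 0.17 h⁻¹) puts the median trough at ≈ 2.4 mg/L — a
one-compartment model cannot match AUC, trough *and* an observed
Cmax ≈ 16 mg/L simultaneously, and the trough is the clinically decisive
metric here, so peak concentrations run low (≈ 9 mg/L) by design. MPAG
clearance 1.22 L/h sets the AUC ratio to ≈ 12 (775/64.7); its volume
0.8 L sets the MPAG trough to ≈ 32 mg/L. Between-subject variability is
lognormal with CVs 0.40 (CL/F), 0.30 (V/F), 0.30 (ka) and 0.40 on the
metabolite clearance — the metabolite gets an *independent* random effect
so that the MPAG/MPA ratio varies across patients as observed (a shared
effect would freeze the ratio). Residual assay error is multiplicative
lognormal, CV 0.10 per sample; concentrations are rounded to 4 significant
digits and floored at 0.

**Covariates.** Age, weight, sex, creatinine (rejection-sampled so the
renal screen passes), albumin, C3/C4, anti-dsDNA, prednisone and therapy
durations are drawn from distributions matching the cohort's median/IQR
summaries; the daily dose follows the empirical mixture 21:2:2:1 over
{2, 1, 3, 1.5} g/day. These covariates are deliberately independent of the
PK random effects — the simulator encodes no covariate-exposure structure,
so null correlation results are the expected behaviour.

**Outcomes.** P(flare) = expit(β₀ + β₁ ln C₁₂ₕ) on the *noise-free* model
trough (the latent exposure), with β₁ = −2.5 by default; β₀ is calibrated
by root-finding so the expected population flare rate is 0.31, evaluated
on a 100,000-draw trough sample from a dedicated deterministic stream
(tolerance 1e-4; with β₁ = 0 the closed form logit(0.31) is returned).
The flare month is drawn with weights (0.04, 0.06, 0.10, 0.20, 0.30,
0.30) over months 1-6, giving median 5 (IQR 4-6). SLEDAI trajectories
encode the label exactly — failures jump by 3-6 points at the flare
month, successes move at most ±1 per visit — so re-deriving outcomes
from visits reproduces the simulator's labels, a pipeline invariant the
tests assert. Prednisone tapers at 10 mg/month from induction-range doses
(> 10 mg/day) and 2 mg/month from maintenance doses, floored at 0.
Patients discontinue (and are excluded) with probability 1/26.

**Reproducibility.** One master seed spawns three child streams in
documented order — patients, profiles, outcomes — so identical configs
produce byte-identical CSVs, and adding patients does not reshuffle
earlier draws within a stream.

**What the simulator does not emulate.** Real MPA kinetics are
multi-compartmental with protein-binding effects; the one-compartment
profile shape (notably Cmax and MPAG Tmax) is only approximate. Covariate
effects on clearance (albumin, renal function, co-medication) are absent,
dosing history/adherence is ideal, and the flare model depends only on the
trough. Passing tests therefore demonstrate the *pipeline's* correctness
and calibration under the assumed structure, not clinical validity on real
cohorts.

## Problem sizes and numerical choices

The test suite exercises: a 30-point (ka × CL) grid for the NCA oracle at
5% tolerance (the 9-point schedule's discretization error peaks around
3% at slow absorption); 1,000 random datasets for the ROC identity at
1e-12; 10,000-replicate Monte-Carlo for the Hanley-McNeil SE; 200
replicate n = 200 cohorts for recovery of a near-deterministic 3 mg/L
boundary (β₁ = −25) into a [2, 4] mg/L window; 2,000 replicate n = 25
null cohorts for type-I error (5% ± 1.5% at α = 0.05); and an n = 10,000
cohort for calibration checks (median MPA AUC within 10% of 64.7 mg·h/L,
calibrated flare rate within 0.005 of 0.31). CSV floats are written at 12
significant digits so read∘write round-trips bit-stably at test
tolerances.

## Known limitations

- The Hanley-McNeil interval is conservative at high AUC (see above).
- The Youden cutoff is reported as an observed score with the rule
  "positive if score < cutoff"; between-observation placement (e.g.
  midpoints) would be equally valid and can shift the reported cutoff by
  up to one inter-observation gap.
- Empirical ROC quantization at n ≈ 25 makes sensitivity/specificity
  granular; confidence intervals on the cutoff itself are out of scope.
- The simulator's exposure-outcome link is through the trough only; AUC
  discriminates in simulation because it correlates with the trough
  through the PK model, mirroring the analysis assumption rather than
  testing it.
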