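# Methods

## The screening algorithm

`cvdrules` implements a guideline-based clinical decision support
algorithm for community cardiovascular (CVD) risk screening, of the
kind run by non-physician health workers on house-to-house visits and
by primary-care physicians in clinic. One screening visit collects 28
raw inputs (demographics, past history, current medications, blood
pressure, anthropometry, and optional point-of-care glucose and lipid
measurements); the engine derives 42 calculated variables from them,
deterministically, ending in a risk category, medication indications,
treatment targets, and referral/lifestyle advice.

### Risk assessment

Ten-year CVD risk is read from a categorical WHO/ISH-style chart over
sex, diabetes status, smoking, an age band, a systolic-BP band and —
when cholesterol was measured — a total-cholesterol band. Five ordered
categories are used: <10%, 10–20%, 20–30%, 30–40%, >40%. Two grids
coexist: *high-information* (with cholesterol) and *low-information*
(without); the lookup selects the pathway purely from cholesterol
availability. Chart age is imputed: ages 18–39 are read at 40, ages
≥79 at 79, so the imputation's image is [40, 79].

The chart band is then *adjusted*:

* **Established CVD** (history of angina/MI, stroke, or peripheral
  vascular disease) overrides everything: category `CVD`, or
  `CVD_AND_CHR` if an extreme factor (below) is also present.
* **Clinically high risk (CHR)** — without established CVD, any of:
  SBP ≥160 mm Hg, DBP ≥100 mm Hg, TC ≥320 mg/dL, LDL-C ≥240 mg/dL, or
  TC/HDL-C ratio strictly >8.
* Otherwise the adjusted category equals the chart band.

Seven **risk-underestimation flags** mark conditions under which the
chart band understates true risk: current antihypertensive therapy;
obesity (BMI ≥27.5 kg/m², the WHO Asian cut-point, or waist ≥90 cm in
men / ≥80 cm in women); family history of premature CHD/stroke;
triglycerides >180 mg/dL; HDL-C <40 mg/dL (men) / <50 mg/dL (women);
fasting dysglycemia (fasting glucose 110–125 mg/dL); and resting
heart rate >100/min. The dysglycemia window and the obesity
definition are package conventions (configurable thresholds in
`RuleThresholds`); the other cut-points are the printed guideline
values.

### Management rules

Diabetes status is known diabetes, fasting glucose ≥126 mg/dL, or
random glucose ≥200 mg/dL. Compound BP thresholds written
"BP ≥160/100" are read disjunctively (SBP ≥160 OR DBP ≥100), and
"risk >20%" / ">30%" are ordinal gates on the adjusted category
(at/above the 20–30% band, resp. the 30–40% band), with the override
categories CHR/CVD/CVD_AND_CHR treated as high risk throughout.

* **BP-lowering** indicated for: established CVD; BP ≥160/100;
  BP ≥140/90 with risk >20%; BP ≥130/80 with risk >30%; or extreme
  lipids (TC ≥320 / LDL ≥240 / ratio >8).
* **Statin** indicated for: established CVD; diabetes; extreme lipids;
  BP ≥160/100; risk >30%; or age ≥40 with risk >20% and TC ≥200 mg/dL
  or LDL-C ≥120 mg/dL.
* **Antiplatelet** indicated for: established atherosclerotic CVD;
  extreme lipids; BP ≥160/100; or risk >30%.
* **Targets.** BP <130/80 mm Hg for CVD, diabetes, or extreme lipids;
  <140/90 for all others. Lipids: TC<160/LDL<80/HDL>45 mg/dL with CVD;
  TC<180/LDL<100/HDL>45 with diabetes; TC<200/LDL<120/HDL>40 otherwise.
* **Referral** for any adjusted category at/above 20–30% (including
  the override categories), any medication indication, or newly
  detected elevated glucose without a known diabetes diagnosis (the
  tool gives no diabetes treatment advice, only "see the doctor").
  Lifestyle advice: smoking cessation for smokers; diet and physical
  activity whenever any elevated risk factor is present (obesity, any
  underestimation flag, any CHR reason, CVD, diabetes, smoking, or a
  chart band at/above 10–20%).

A rule whose optional input was not measured is false — missingness
never triggers care — and the corresponding calculated variables carry
an explicit `NE` (not evaluable) marker rather than a silent default.
This closes the classic incoherent-missing-data bug class in
hand-coded clinical algorithms.

## The bundled chart and its limits

Published WHO/ISH chart values are copyrighted tables and are not
redistributed. The bundled chart (`data/synthetic_chart.csv`, also
available as `synthetic_chart_set()`) is a synthetic, monotone
stand-in with the standard grid shape: age bands [40,50), [50,60),
[60,70), [70,∞) (chart age never exceeds 79); SBP bands (−∞,140),
[140,160), [160,180), [180,∞) mm Hg; cholesterol bands (−∞,4), [4,5),
[5,6), [6,7), [7,∞) mmol/L (mg/dL inputs divided by 38.67). Its cell
values come from a positive-weight linear score, so risk is monotone
non-decreasing in every audited direction by construction. Band
boundaries are read from the chart file, not hard-coded, so a user can
transcribe a published chart (any region, either cholesterol unit)
into the same CSV format. All shipped tests run against the synthetic
chart; nothing about agreement on it certifies the *clinical* accuracy
of any particular published chart transcription — `cvdrules
chart-check` audits a transcription for monotonicity violations but
cannot detect a wrongly copied yet monotone cell.

## Validation design

Validation follows the dual-implementation protocol used for clinical
decision support tools: the plain-language rules are coded twice — the
production engine, and a deliberately flat, exhaustively sequential
decision table (`validation.oracle_assess`) with its own literal
constants and its own chart-cell search (interval-containment scan
rather than band arithmetic). `compare_cohort` runs both on every
record and reports per-variable agreement over the 42 calculated
variables; release criterion is 42/42 at agreement 1.0. Floating-point
variables (BMI, TC in mmol/L, TC/HDL ratio, imputed age) compare with
absolute tolerance 1e-9; everything else compares exactly, and `NE`
agrees only with `NE`.

The deterministic **boundary suite** (`cohort.boundary_suite()`, 120
records) places every threshold at offsets −1/0/+1 (the TC/HDL ratio
at 7.9/8.0/8.1), each history flag as a singleton, every missingness
pattern of the optional fields, and compound cases that probe the
BP-rule and statin-gate boundaries inside the risk-band contexts where
those rules are decisive. Fault-injection tests (`RuleThresholds`
overrides on the engine side only) confirm the suite kills single
threshold mutations and that the induced disagreements stay inside the
mutated threshold's dependency closure.

`export_review_worksheet` supports the complementary human validation
step: a seeded random sample of cases with blank adjudication columns
for manual chart reading, plus an engine answer key.

## Synthetic cohorts

`generate_cohort` is a pure function of `CohortParams` (seed
included). Default marginals emulate a rural community screening
population: age truncated-normal 51.4 (SD 13.1) years on [18,110]; 67%
female; 13% smokers; history rates 16% angina/MI, 1% stroke, 10% PVD,
14% diabetes, 19% on BP-lowering therapy, 10% family history; SBP mean
129 (SD 22) mm Hg with a +0.4 mm Hg/year age slope (residual SD chosen
to preserve the marginal SD); DBP mean 80 (SD 12), generated partly
from SBP and clipped below it; BMI truncated-normal 24.2 (SD 4.6)
kg/m² with weight derived from height (normal 155/165 ± 8 cm by sex).
Laboratory values are lognormal (right-skewed, as lipid and glucose
panels are), with medians TC 185, HDL 42, LDL 110, TG 140, fasting
glucose 100, random glucose 125 mg/dL; known diabetics draw glucose
scaled ×1.5. The four lipid values are jointly missing with
probability 1 − `p_cholesterol_available` (default 0.3), mirroring
intermittent availability of a point-of-care lipid test; each record
carries either a fasting or a random glucose. Correlations beyond the
SBP–age slope and the DBP–SBP coupling are omitted.

What the generator does **not** emulate: measurement error and digit
preference in field BP readings, village-level clustering, informative
missingness (sicker patients measured more), or over-reporting of PVD
by screeners. Passing dual-implementation validation on synthetic
cohorts therefore certifies the *logic*, not field data quality.

## Cascade analytics

`compute_cascade` counts the screening → referral → BP-medication
indication → 1-month clinic attendance → doctor recommendation →
3-month adherence pathway from engine output joined (strictly, by
participant id) to follow-up records. Stage percentages are always
taken over the immediately preceding stage and printed as integers
rounded half-up. When the doctor-recommendation stage was not captured
(`recommended=None` in `CascadeCounts`), the adherence link is taken
over attendance. Records whose high-risk status rests on a reported
PVD history alone (PVD without angina/MI/stroke, no extreme factor,
chart band below 20–30%) can be excluded with a flag, since field
screeners are known to over-report PVD. `bp_management_summary`
reports clinic-side BP management: the share already on BP-lowering
therapy, the share of those strictly below their assigned BP target
(SBP and DBP both), and the share of untreated patients with an engine
indication.

## Numerical and design choices

* All bands are half-open [lo, hi); the topmost band closes at +∞.
* Printed operators are applied literally: ≥ inclusive, > strict.
* Cholesterol conversion: mg/dL ÷ 38.67 → mmol/L, applied before
  banding when the chart declares mmol/L.
* The TC/HDL ratio is evaluable only when both values are present and
  HDL > 0.
* "Established atherosclerotic CVD" (the antiplatelet criterion) is
  taken as identical to established CVD (angina/MI, stroke, PVD); the
  engine does not attempt to separate embolic from atherosclerotic
  stroke from a lay-administered history.
* Glucose and cholesterol are stored in mg/dL internally; BMI is
  weight/(height/100)².
* Malformed rows in patient input files are warned about and skipped
  (field data entry is error-prone); chart files fail hard on any
  format or completeness defect.

## Problem sizes

The shipped test suite and the reproduction script use the 120-record
boundary suite and synthetic cohorts of 1,000 records (10,000 for the
marginal-convergence check); the full suite runs in a few seconds on
one CPU. These sizes give binomial standard errors well below the
tolerances asserted (e.g. mean SBP within ±3 mm Hg at n=1000).

## Known limitations

* The bundled chart is synthetic; clinical use requires transcribing a
  published, calibrated chart.
* The 42-variable registry is this package's normative enumeration of
  the derived quantities the rules need; other implementations of the
  same guideline logic may factor them differently.
* No drug dosing, interaction checking, or diabetes management beyond
  referral; no continuous (equation-based) risk scores.
* Cascade analytics assume one screening encounter per participant;
  longitudinal visit histories are out of scope.
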