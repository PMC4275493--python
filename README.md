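# cvdrules

A guideline rules engine for community cardiovascular disease (CVD)
risk screening, built for settings where screening is task-shifted to
non-physician health workers: categorical WHO/ISH-style 10-year risk
chart lookup, management indications and treatment targets, a
dual-implementation validation harness, reproducible synthetic
screening cohorts, and care-cascade analytics.

## Who this is for

Implementers and evaluators of clinical decision support for CVD
screening programs: people who need the screening algorithm itself as
a tested, auditable library (not embedded in an app), a way to
*validate* a coded algorithm against an independent implementation,
and tools to analyse the screening → referral → treatment cascade that
such programs produce.

## The algorithm

One screening visit yields 28 inputs. The engine derives 42 calculated
variables ending in:

* a **10-year risk category** from a categorical chart over
  (sex, diabetes, smoking, age band, SBP band, [cholesterol band]),
  with chart age imputed into [40, 79] and automatic fallback to the
  low-information chart when cholesterol was not measured;
* an **adjusted category**: established CVD (angina/MI, stroke, PVD)
  and extreme single factors (SBP ≥160, DBP ≥100 mm Hg, TC ≥320,
  LDL ≥240 mg/dL, TC/HDL >8 — "clinically high risk", CHR) override
  the chart band;
* **risk-underestimation flags** (antihypertensive therapy, obesity,
  family history, TG >180 mg/dL, low HDL, fasting dysglycemia, heart
  rate >100/min);
* **medication indications** (BP-lowering, statin, antiplatelet),
  **targets** (BP <130/80 mm Hg for CVD/diabetes/extreme lipids, else
  <140/90; three lipid tiers), and **referral/lifestyle advice**.

Rules never fire on missing inputs; unmeasured derived variables carry
an explicit `NE` marker. Full details are in
[`docs/methods.md`](docs/methods.md).

The bundled chart is a synthetic, monotone stand-in with the standard
grid shape (published WHO/ISH chart values are not redistributed);
transcribe a published chart into the documented CSV format for
clinical use.

## Worked example

```python
from cvdrules import PatientRecord, assess_patient, synthetic_chart_set

record = PatientRecord(
    participant_id="P0042", assessment_date="2014-03-01",
    assessor_role="NPHW", village_code="V03",
    age=58, sex="male", current_smoker=True,
    hx_angina_or_mi=False, hx_stroke=False, hx_pvd=False,
    hx_diabetes=False, fam_hx_premature_chd_or_stroke=False,
    on_bp_lowering=False, on_lipid_lowering=False, on_antiplatelet=False,
    sbp=168, dbp=96, heart_rate=88, height=168, weight=78, waist=96,
    glucose_is_fasting=True, fasting_glucose=118, random_glucose=None,
    tc=232, ldl=150, hdl=38, tg=210,
)
result = assess_patient(record, synthetic_chart_set())
```

which prints, via `cvdrules.io.write_patient_report`:

```
participant_id: P0042
adjusted_risk_category: CHR
chart_risk_category: R20_30
pathway: high_info
chr_reasons: SBP>=160
underestimation_flags: fasting_dysglycemia;low_hdl;obesity;raised_tg
bp_med_indicated: True
statin_indicated: True
antiplatelet_indicated: True
bp_target: <140/90 mm Hg
lipid_targets: TC<200 LDL<120 HDL>40 mg/dL
referral_indicated: True
lifestyle_advice: diet;physical_activity;smoking_cessation
```

Reading this: a 58-year-old male smoker with SBP 168 mm Hg is
clinically high risk (`CHR`) regardless of his chart band (`R20_30`,
read from the high-information chart since cholesterol was measured);
his SBP ≥160 alone indicates BP-lowering, statin, and antiplatelet
therapy and referral; four conditions (fasting glucose 118, HDL 38,
BMI 27.6, TG 210) flag his chart risk as underestimated; his targets
are the standard tier because he has no established CVD, diabetes, or
extreme lipids.

## Command line

```sh
cvdrules simulate --out cohort.csv --n 200 --seed 7
cvdrules assess   --in cohort.csv --out assessed.csv
cvdrules validate --out agreement.csv --n 500 --seed 7
cvdrules cascade  --in cohort.csv --followup fu.csv --out cascade.txt
cvdrules chart-check --chart mychart.csv
```

`assess` writes one row per patient (42 calculated variables plus
reason codes) and logs indication counts, e.g.
`assessed=200 skipped=0 bp_med=85 statin=109 antiplatelet=83
referral=109`. `validate` compares the engine against an independently
coded flat decision table over the deterministic threshold-boundary
suite plus a synthetic cohort and exits non-zero unless all 42
variables agree fully: `42/42 variables agree on 620 records`.

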