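# score2modes

Compare the two clinical modes of applying the SCORE2 10-year
cardiovascular risk model — the unrounded **online calculator** and the
quantized paper **risk chart** — with full competing-risk validation and
treatment-impact estimation.

SCORE2 estimates the 10-year risk of a first cardiovascular event
(cardiovascular death, non-fatal myocardial infarction or stroke) for
adults aged 40–69 without prior CVD or diabetes from six risk factors:
age, sex, current smoking, systolic blood pressure (SBP), total and HDL
cholesterol. It is a sex-specific proportional-hazards algorithm,

    risk_uncal = 1 − S0^exp(Σ_k β_k x_k),

recalibrated to one of four European risk regions on the complementary
log-log scale, `risk = 1 − exp(−exp(scale1 + scale2·ln(−ln(1 −
risk_uncal))))`. In practice the model reaches clinicians in two forms
that are recommended interchangeably but do not agree: the calculator
evaluates the formula exactly, while the chart rounds age to 5-year
groups, SBP to 20 mmHg bands and non-HDL cholesterol (TC − HDL) to
1 mmol/L bands, scores the cell midpoint, and prints a whole percent.
This package is for biostatisticians and prevention researchers who want
to quantify what that quantization does to discrimination (competing-risk
Harrell's C), calibration (Aalen–Johansen incidence by decile of
predicted risk), reclassification (censoring-adjusted categorical NRI),
decision-curve net benefit, and treatment eligibility under the
guideline thresholds (≥7.5% at ages 40–49, ≥10% at 50–69 — effectively
≥9.5% on the chart, because 9.5 prints as 10).

Because the source cohorts behind such comparisons are not publicly
deposited, the package includes a simulator that generates cohorts with
matching risk-factor distributions and a competing-risk outcome structure
in which each individual's true 10-year CVD incidence *equals* their
calculator risk — so ground truth is known, perfect calibration is the
null, and every downstream estimator is testable end to end.

## Worked example

```python
from score2modes import (RiskProfile, calculator_risk, chart_risk,
                         default_model_spec, quantize_profile)

spec = default_model_spec()
person = RiskProfile(age=58, sex="male", smoker=True, sbp=138, tchol=6.1, hdl=1.45)
cell = quantize_profile(person)   # age 57.5, SBP 130, non-HDL 4.5
for region in ("low", "moderate", "high", "very_high"):
    print(region, round(100 * calculator_risk(person, spec, region), 2),
          chart_risk(person, spec, region))
```

prints (calculator %, chart %):

```
low 8.11 8
moderate 10.57 10
high 11.99 11
very_high 19.58 18
```

The same person, same model: the chart scores the midpoint of his cell
(57.5 years, 130 mmHg, non-HDL 4.5) and rounds, shifting the estimate by
up to 1.6 percentage points here. In the moderate region he sits exactly
at the ≥10% treatment threshold under both modes; elsewhere the two
modes can disagree on eligibility.

The `examples/` directory holds one short script per capability:

* `compute_risk.py` — score one individual in both modes, all regions;
* `render_chart.py` — print a full chart stratum as whole-percent cells;
* `simulate_and_validate.py` — simulate a cohort, compare C-statistics
  (calculator ≈ 0.654 vs chart ≈ 0.646 at n = 20 000, ΔC ≈ +0.009) and
  show calibration by decile;
* `treatment_impact.py` — eligibility overlap and events prevented per
  1000 treated under a hazard ratio of 0.5 (the chart marks more people
  eligible; the calculator-eligible group is higher-risk, so it yields
  more events prevented per 1000 treated).

A thin CLI wraps the same functions:

```
score2modes simulate --preset low_region --n 20000 --seed 1 --out cohort.tsv
score2modes score cohort.tsv --out scored.tsv
score2modes chart --region moderate --sex male --smoker
score2modes run-all --outdir reports --seed 1 --n 20000
```

`run-all` writes, per cohort group, the characteristics, discrimination
(overall and by sex, with paired-bootstrap ΔC confidence intervals),
calibration, NRI, net benefit, eligibility overlap and impact tables,
plus a JSON summary; reruns with the same seed are byte-identical.

## Model configuration

Coefficients, baseline survivals and regional recalibration scales are an
editable YAML file (`src/score2modes/data/score2_coefficients.yaml`)
holding the published SCORE2 values; `load_model_spec` validates
completeness so alternative coefficient sets can be swapped in. See
`docs/methods.md` for the estimators, simulator design and numerical
choices.
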