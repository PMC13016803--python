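# Methods

`score2modes` compares the two ways the SCORE2 10-year cardiovascular risk
model is applied in clinical practice — as an unrounded algorithm ("online
calculator") and as a printed two-dimensional risk chart — and quantifies
what the chart's quantization costs in discrimination, calibration,
reclassification, decision-curve net benefit and treatment targeting. This
note documents the models, estimators, numerical choices and known
limitations.

## The risk model and the two application modes

SCORE2 is a sex-specific proportional-hazards algorithm for the 10-year
risk of a first cardiovascular event (cardiovascular death, non-fatal
myocardial infarction or stroke) in people aged 40–69 without prior CVD or
diabetes. For raw covariates age, current smoking, systolic blood pressure
(SBP), total and HDL cholesterol, each continuous covariate is centred and
scaled, e.g. transformed age = (age − 60)/5, and the linear predictor is

    lp = Σ_k β_k x_k

over the five main effects and the four age-interaction products. The
uncalibrated 10-year risk is `1 − S0^exp(lp)` with sex-specific baseline
survival S0, and regional recalibration maps it through the complementary
log-log scale:

    risk = 1 − exp(−exp(scale1 + scale2 · ln(−ln(1 − risk_uncal))))

with one (scale1, scale2) pair per risk region (low / moderate / high /
very high) and sex. All coefficients, S0 values and scales live in an
editable YAML configuration (`score2modes/data/score2_coefficients.yaml`)
holding the published SCORE2 values; the loader validates completeness
(both sexes, all nine terms, all four regions, S0 ∈ (0,1), scale2 > 0) but
deliberately not the numbers, so alternative coefficient sets can be
plugged in. A consistency check: the packaged configuration reproduces the
published worked example (50-year-old male smoker, SBP 140, TC 6.3, HDL
1.4, low-risk region → 6.3%).

**Calculator mode** evaluates this formula on the exact inputs and returns
a continuous fraction.

**Chart mode** reproduces what a clinician reads off the printed chart:
age is replaced by the midpoint of its 5-year group (so everyone aged
60–64 is scored at 62.5), SBP by the midpoint of its 20 mmHg band, and the
two cholesterol values are first collapsed to non-HDL = TC − HDL and then
replaced by the midpoint of the 1 mmol/L band; the resulting risk is
rounded **half-up** to a whole percent. Design choices here:

* *Bin layout.* Age [40,45)…[65,70), SBP [100,120)…[160,180), non-HDL
  [3,4)…[6,7), all half-open, midpoints strictly inside. Values outside
  the grid are clamped to the boundary bin with a warning — mimicking a
  clinician using the extreme row/column of a paper chart — rather than
  rejected.
* *Cholesterol collapse.* The chart has a single non-HDL axis but the
  model has separate TC and HDL coefficients. The cell midpoint is fed to
  the formula by pinning HDL at its centering constant (1.3 mmol/L) and
  setting TC = midpoint non-HDL + 1.3. This is done in exactly one place
  (`quantize_profile`) so an alternative chart construction (e.g. a
  dedicated non-HDL coefficient) would be a one-function change. A direct
  consequence, preserved by design: two people with TC/HDL of 6.0/1.5 and
  5.5/1.0 share a chart cell (non-HDL 4.5) but have different calculator
  risks.
* *Rounding.* Half-up, never banker's: a 9.5% cell prints as 10% and is
  treatment-eligible at the ≥10% threshold, which makes 9.5% the
  *effective* chart threshold at ages 50–69.

## Synthetic cohorts

The simulator generates the two kinds of population the comparison needs:
`low_region` (a large primary-care population in Europe's low-risk region:
mean age 53, SD 8; 49% male; 45% smokers; SBP 132 (16); TC median 5.5,
quartiles 4.8–6.2; HDL 1.4, 1.2–1.7) and `high_region` (an
Eastern-European cohort pooled 64%/36% over the high and very-high
regions: mean age 57 (7), ages 45–69; 45% male; 25% smokers; SBP 137
(20); TC 5.8, 5.2–6.5). Choices:

* Ages are whole years (people report integer ages to a calculator),
  drawn from a truncated normal whose underlying parameters are
  moment-matched so the *truncated* distribution has the stated mean and
  SD — sampling with the raw parameters would bias the mean upward by
  ~0.5 years at these truncation points.
* Cholesterol is log-normal, fitted by matching log-median and log-IQR to
  the stated median/quartiles; pairs are redrawn until TC > HDL.
* Outcomes follow constant cause-specific hazards over the 10-year
  horizon: λ2 (non-CVD death) is a population parameter, and λ1 (CVD) is
  solved per individual (vectorised Newton from the λ2 = 0 closed form
  −ln(1−r)/10) so that the CVD cumulative incidence
  λ1/(λ1+λ2)·(1−e^(−10(λ1+λ2))) equals the individual's calculator risk.
  Truth therefore equals prediction, perfect calibration is the null, and
  the 10-year CVD incidence is invariant to λ2 by construction.
  Miscalibration can be injected with a multiplicative hazard distortion
  (default 1.0).
* λ2 defaults: 0.003/yr (low preset) and 0.009/yr (high preset), chosen so
  the simulated non-CVD death fractions sit near the study populations'
  reported counts (~2% and ~8% over the observed follow-up).
* Censoring is uniform administrative-style: [5, 12] years (low; median
  follow-up ≈ 8.4 y) and [5.5, 11.5] years (high; median ≈ 8.0 y). The
  presets target the reported medians only, not the full follow-up
  distribution.
* All randomness flows from one seed via `SeedSequence.spawn`; no global
  state.

What the simulator does **not** emulate: covariate correlations (risk
factors are drawn independently), missing data and imputation,
non-proportional or time-varying hazards, covariate-dependent censoring,
and real-world departures of observed incidence from model predictions.
Passing tests on these cohorts therefore demonstrate the *mechanics* of
the comparison (quantization loses concordant pairs, the chart's effective
thresholds widen eligibility, calibration machinery recovers truth) — not
that any real population is well calibrated.

## Validation estimators

All estimators handle the three-state outcome (0 censored, 1 CVD, 2
non-CVD death) explicitly and are implemented from first principles.

* **Cumulative incidence** is Aalen–Johansen: at each event time,
  CIF₁ += S(t−)·d₁/n. The product-limit construction guarantees
  CIF₁ + CIF₂ + S = 1 at every step (tested to 1e−12); the variance is the
  standard product-limit (Marubini–Valsecchi) estimator. Both the point
  estimate and the variance agree with lifelines'
  `AalenJohansenFitter` on random data, used as an independent oracle in
  tests only.
* **Harrell's C, competing-risk adaptation.** A pair (i, j) is comparable
  when i has a CVD event and either t_i < t_j or j died of a non-CVD
  cause at *any* time — competing-event subjects are known never to fail
  from CVD and are treated as censored at +∞ (the alternative, censoring
  them at death, is available via `competing='censor'`). Prediction ties
  count 0.5; tied event times are not comparable. The implementation
  counts pairs with a Fenwick tree in O(n log n) (≈0.25 s at n = 100 000)
  and agrees *exactly* with a brute-force O(n²) double loop at n ≤ 2000,
  including heavy ties. CIs by seeded bootstrap; ΔC (calculator − chart)
  uses a paired bootstrap over individuals.
* **Calibration** splits the sample into 10 equal-count groups by
  predicted risk (stable sort) and compares mean predicted risk with the
  group's Aalen–Johansen incidence at 10 years. Whole-percent chart risks
  often have fewer than 10 distinct values; grouping then falls back to
  one group per distinct value, with a warning.
* **Categorical NRI** uses the guideline categories <5%, 5–<10%, ≥10%.
  Each cell of the cross-classification gets an Aalen–Johansen event
  probability by the horizon, so expected event/non-event counts replace
  naive counting (which is biased under censoring):
  NRI_events = (expected events up − down)/expected events, and
  symmetrically for non-events; overall is the sum. On fully observed
  data this reduces exactly to the textbook up/down counting formula.
  Empty cells contribute 0 with a warning. CIs by seeded bootstrap
  (default 500 replicates; configurable).
* **Net benefit** at threshold p_t:
  NB = P(risk ≥ p_t ∧ event) − w·P(risk ≥ p_t ∧ no event), the joint
  probabilities estimated by Aalen–Johansen inside the high-risk
  subgroup. The default weight is the exact threshold odds
  w = p_t/(1−p_t) = 1/9 at p_t = 0.10; a "1-in-10" literal weight of 0.1
  is one argument away (`weight=0.1`), since published descriptions of
  the 1:10 weighting are ambiguous between the two.

## Treatment eligibility and impact

Eligibility follows the age-specific very-high-risk thresholds: ≥7.5% at
ages 40–49 and ≥10% at 50–69, age banded on floor(age) at baseline. The
calculator compares the unrounded fraction; the chart compares the printed
whole percent, making its effective thresholds 7.5% and 9.5%. Expected
impact of treating the eligible group combines its observed 10-year
Aalen–Johansen incidence with a treatment hazard ratio (default 0.50) on
the hazard scale: treated incidence = 1 − (1 − CIF)^hr. This is the
standard survival-analysis reading of "applying a hazard ratio"; the
naive alternative CIF × hr is available via `hr_scale='linear'`. Prevented
counts and per-1000-treated values round to the nearest integer. To first
order, prevented-per-person ≈ CIF/2 at hr = 0.5 for small CIF (relative
gap < 3% below CIF = 0.05, tested).

## Pipeline and reproducibility

`pipeline.run` executes simulate/load → score → validate → impact for each
cohort group (high and very-high regions are pooled, as mixed
Eastern-European cohorts are analysed), writing delimited-text reports and
one JSON summary. A single master seed fans out via
`numpy.random.SeedSequence.spawn` to the simulation and bootstrap stages,
so two runs with the same configuration are byte-identical (tested). The
cohort-file schema is strict — sex ∈ {M, F}, event ∈ {0, 1, 2}, ages in
[40, 70) — and violations are reported with row and column; all tables are
computed before any file is written, so failures leave no partial reports.

## Problem sizes

Unit and property tests run at n = 1200–2000 (where the O(n²) concordance
oracle is exact and fast); distributional and direction-preserving checks
use the full low-region preset (n = 100 000) or n = 20 000–50 000 where a
Monte-Carlo tolerance of 3 standard errors is the acceptance band. The
examples use n = 20 000 to keep each script in seconds. Default bootstrap
replicates are 200 in the pipeline (500 in the standalone NRI), reduced in
tests where only determinism, not CI width, is under test.

## Known limitations

* The C-statistics on simulated cohorts (~0.65 in the low preset) are
  lower than those reported for real primary-care populations (~0.75),
  because independent covariates with integer ages span less risk
  gradient than a real cohort; the *difference* between modes, which is
  what the package measures, is insensitive to this.
* Constant cause-specific hazards are a deliberate simplification; with
  hazards this smooth, the Aalen–Johansen and naive estimators differ
  less than they would under clustered censoring.
* The chart's cholesterol collapse is one published-chart reading; the
  construction is isolated so it can be swapped if the published cell
  values are found to differ.
* No multiple imputation: synthetic cohorts are complete-case by design.
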