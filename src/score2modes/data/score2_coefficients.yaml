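# SCORE2 model configuration: sex-specific log-hazard-ratio coefficients for
# the transformed risk factors, sub-distribution baseline 10-year survival,
# and the four-region recalibration scales applied on the complementary
# log-log scale. Values transcribed from the published SCORE2 algorithm
# (SCORE2 working group / ESC Cardiovascular Risk Collaboration, 2021).
# Edit this file (or point the loader at a copy) to use alternative
# coefficient sets; the loader validates completeness, not the numbers.

transforms:
  age:   {center: 60.0, divisor: 5.0}
  sbp:   {center: 120.0, divisor: 20.0}
  tchol: {center: 6.0, divisor: 1.0}
  hdl:   {center: 1.3, divisor: 0.5}

coefficients:
  male:
    age: 0.3742
    smoking: 0.6012
    sbp: 0.2777
    tchol: 0.1458
    hdl: -0.2698
    smoking_x_age: -0.0755
    sbp_x_age: -0.0255
    tchol_x_age: -0.0281
    hdl_x_age: 0.0426
  female:
    age: 0.4648
    smoking: 0.7744
    sbp: 0.3131
    tchol: 0.1002
    hdl: -0.2606
    smoking_x_age: -0.1088
    sbp_x_age: -0.0277
    tchol_x_age: -0.0226
    hdl_x_age: 0.0613

baseline_survival:
  male: 0.9605
  female: 0.9776

recalibration:
  low:
    male:   {scale1: -0.5699, scale2: 0.7476}
    female: {scale1: -0.7380, scale2: 0.7019}
  moderate:
    male:   {scale1: -0.1565, scale2: 0.8009}
    female: {scale1: -0.3143, scale2: 0.7701}
  high:
    male:   {scale1: 0.3207, scale2: 0.9360}
    female: {scale1: 0.5710, scale2: 0.9369}
  very_high:
    male:   {scale1: 0.5836, scale2: 0.8294}
    female: {scale1: 0.9412, scale2: 0.8329}

# Chart grid: half-open bins [lo, hi); predictions inside a cell use the cell
# midpoint. Widths follow the published chart: 5-year age groups, 20 mmHg
# systolic blood pressure bands, 1 mmol/L non-HDL cholesterol bands.
grid:
  age_edges: [40, 45, 50, 55, 60, 65, 70]
  sbp_edges: [100, 120, 140, 160, 180]
  nonhdl_edges: [3, 4, 5, 6, 7]
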