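"""Render a full risk-chart stratum as whole-percent cells.

Reproduces the layout of a printed two-dimensional risk chart for one
(region, sex, smoking) stratum: 5-year age groups, 20 mmHg SBP bands and
1 mmol/L non-HDL cholesterol bands, each cell the rounded 10-year risk at
the cell midpoints.
"""

from score2modes import default_model_spec, render_chart
from score2modes.engine import chart_text

spec = default_model_spec()
table = render_chart(spec, region="moderate", sex="male", smoker=True)
print("moderate risk region, male, current smoker\n")
print(chart_text(table))
print(
    "Rows are SBP bands (midpoints, high to low), columns non-HDL bands;"
    "\neach number is the 10-year CVD risk (%) a clinician would read off"
    "\nthe chart for anyone falling in that cell."
)
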