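"""Treatment eligibility and expected events prevented.

The 2021 ESC prevention guidelines mark 10-year CVD risk >= 7.5% (ages
40-49) or >= 10% (ages 50-69) as "very high risk: treatment generally
recommended". The two application modes disagree near the threshold:
the calculator compares the unrounded fraction, while the chart compares
the whole-percent cell value, so an unrounded cell risk of 9.5% is read as
10% on the chart and becomes treatment-eligible.

Expected impact of treating the eligible group is computed from its observed
10-year cumulative incidence (Aalen-Johansen) combined with a treatment
hazard ratio, by default on the hazard scale:
treated incidence = 1 - (1 - CIF)^hr.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .validation import aalen_johansen

__all__ = [
    "EligibilityDecision",
    "ImpactSummary",
    "band_threshold",
    "classify",
    "classify_cohort",
    "eligibility_overlap",
    "events_prevented",
    "impact_report",
    "events_prevented_per_1000",
]

THRESHOLD_YOUNG = 0.075  # ages 40-49
THRESHOLD_OLD = 0.10  # ages 50-69


@dataclass(frozen=True)
class EligibilityDecision:
    method: str  # 'calculator' or 'chart'
    eligible: bool
    threshold: float
    age_band: str  # '40-49' or '50-69'


@dataclass(frozen=True)
class ImpactSummary:
    method: str
    n_cohort: int
    n_eligible: int
    pct_eligible: float
    cif10: float
    hazard_ratio: float
    treated_incidence: float
    events_prevented: int
    per_1000_treated: int


def band_threshold(age: float) -> tuple[str, float]:
    """Guideline age band and its very-high-risk threshold (age floored)."""
    if not (40.0 <= age < 70.0):
        raise ValueError(f"age {age} outside the 40-69 assessment range")
    if int(np.floor(age)) < 50:
        return "40-49", THRESHOLD_YOUNG
    return "50-69", THRESHOLD_OLD


def classify(
    age: float, calculator_risk: float, chart_risk: int, method: str
) -> EligibilityDecision:
    """Treatment eligibility for one individual under one mode.

    Calculator mode compares the unrounded fraction with the band threshold
    (>=). Chart mode compares the whole-percent chart value with the
    threshold expressed in percent (>=), so chart 10 qualifies at the 10%
    threshold even when the unrounded cell risk was 9.5%.
    """
    band, thr = band_threshold(age)
    if method == "calculator":
        eligible = calculator_risk >= thr
    elif method == "chart":
        eligible = chart_risk >= 100.0 * thr
    else:
        raise ValueError("method must be 'calculator' or 'chart'")
    return EligibilityDecision(method, bool(eligible), thr, band)


def classify_cohort(
    age: np.ndarray, calculator_risk: np.ndarray, chart_risk: np.ndarray, method: str
) -> np.ndarray:
    """Vectorised eligibility flags for a cohort."""
    age = np.asarray(age, dtype=float)
    if np.any((age < 40) | (age >= 70)):
        bad = int(np.argmax((age < 40) | (age >= 70)))
        raise ValueError(f"age outside 40-69 at row {bad}: {age[bad]}")
    thr = np.where(np.floor(age) < 50, THRESHOLD_YOUNG, THRESHOLD_OLD)
    if method == "calculator":
        return np.asarray(calculator_risk, dtype=float) >= thr
    if method == "chart":
        return np.asarray(chart_risk, dtype=float) >= 100.0 * thr
    raise ValueError("method must be 'calculator' or 'chart'")


def eligibility_overlap(
    eligible_calc: np.ndarray,
    eligible_chart: np.ndarray,
    time: np.ndarray | None = None,
    event: np.ndarray | None = None,
    horizon: float = 10.0,
) -> pd.DataFrame:
    """2x2 partition of the cohort by the two eligibility decisions.

    Rows: both, chart_only, calculator_only, neither; counts always
    partition the cohort. When follow-up data is supplied, the observed
    10-year cumulative incidence within each group is added.
    """
    eligible_calc = np.asarray(eligible_calc, dtype=bool)
    eligible_chart = np.asarray(eligible_chart, dtype=bool)
    if len(eligible_calc) != len(eligible_chart):
        raise ValueError("eligibility vectors must be aligned")
    groups = {
        "both": eligible_calc & eligible_chart,
        "chart_only": ~eligible_calc & eligible_chart,
        "calculator_only": eligible_calc & ~eligible_chart,
        "neither": ~eligible_calc & ~eligible_chart,
    }
    rows = []
    for name, mask in groups.items():
        row = {"group": name, "n": int(mask.sum())}
        if time is not None and event is not None:
            if mask.any():
                row["cif10"], _ = aalen_johansen(
                    np.asarray(time)[mask], np.asarray(event)[mask], horizon
                )
            else:
                row["cif10"] = np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    assert int(out["n"].sum()) == len(eligible_calc)
    return out


def events_prevented(
    cif10: float,
    n_eligible: int,
    hr: float = 0.5,
    method: str = "calculator",
    hr_scale: str = "hazard",
) -> ImpactSummary:
    """Expected event reduction from treating the eligible group.

    ``hr_scale='hazard'`` (default) applies the hazard ratio on the
    complementary-log scale of the event process:
    treated incidence = 1 - (1 - CIF)^hr. ``hr_scale='linear'`` multiplies
    the cumulative incidence by hr directly.
    """
    if not (0.0 <= cif10 < 1.0):
        raise ValueError("cif10 must be in [0, 1)")
    if not (0.0 < hr <= 1.0):
        raise ValueError("hazard ratio must be in (0, 1]")
    if hr_scale == "hazard":
        treated = 1.0 - (1.0 - cif10) ** hr
    elif hr_scale == "linear":
        treated = cif10 * hr
    else:
        raise ValueError("hr_scale must be 'hazard' or 'linear'")
    prevented_pp = cif10 - treated
    prevented = int(np.rint(n_eligible * prevented_pp))
    per_1000 = events_prevented_per_1000(prevented, n_eligible)
    return ImpactSummary(
        method=method,
        n_cohort=0,
        n_eligible=int(n_eligible),
        pct_eligible=np.nan,
        cif10=float(cif10),
        hazard_ratio=float(hr),
        treated_incidence=float(treated),
        events_prevented=prevented,
        per_1000_treated=per_1000,
    )


def events_prevented_per_1000(prevented: int, n_eligible: int) -> int:
    """Events prevented per 1000 treated, rounded to the nearest integer."""
    if n_eligible == 0:
        return 0
    return int(np.rint(1000.0 * prevented / n_eligible))


def impact_report(
    cohort: pd.DataFrame,
    pairs: pd.DataFrame,
    hr: float = 0.5,
    horizon: float = 10.0,
    hr_scale: str = "hazard",
    group_label: str | None = None,
) -> pd.DataFrame:
    """Eligibility and expected event reduction for both modes.

    ``cohort`` needs columns age, time, event; ``pairs`` the aligned
    calculator_risk (fraction) and chart_risk (integer percent). One row per
    method with eligible n and %, observed 10-year cumulative incidence in
    the eligible group, events prevented, and per-1000-treated.
    """
    n = len(cohort)
    rows = []
    for method in ("calculator", "chart"):
        eligible = classify_cohort(
            cohort["age"].to_numpy(),
            pairs["calculator_risk"].to_numpy(),
            pairs["chart_risk"].to_numpy(),
            method,
        )
        n_el = int(eligible.sum())
        if n_el == 0:
            warnings.warn(f"no treatment-eligible individuals under {method} mode")
            summary = ImpactSummary(method, n, 0, 0.0, 0.0, hr, 0.0, 0, 0)
        else:
            cif10, _ = aalen_johansen(
                cohort["time"].to_numpy()[eligible],
                cohort["event"].to_numpy()[eligible],
                horizon,
            )
            # product-limit estimate can hit 1.0 exactly in tiny groups
            cif10 = min(cif10, 1.0 - 1e-12)
            base = events_prevented(cif10, n_el, hr, method, hr_scale)
            summary = ImpactSummary(
                method=method,
                n_cohort=n,
                n_eligible=n_el,
                pct_eligible=100.0 * n_el / n,
                cif10=base.cif10,
                hazard_ratio=hr,
                treated_incidence=base.treated_incidence,
                events_prevented=base.events_prevented,
                per_1000_treated=base.per_1000_treated,
            )
        row = {
            "method": summary.method,
            "n_cohort": summary.n_cohort if summary.n_cohort else n,
            "n_eligible": summary.n_eligible,
            "pct_eligible": summary.pct_eligible,
            "cif10_eligible": summary.cif10,
            "hazard_ratio": summary.hazard_ratio,
            "events_prevented": summary.events_prevented,
            "per_1000_treated": summary.per_1000_treated,
        }
        if group_label is not None:
            row = {"group": group_label, **row}
        rows.append(row)
    return pd.DataFrame(rows)
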