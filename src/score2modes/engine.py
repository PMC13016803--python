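"""SCORE2 risk engine: calculator mode and risk-chart mode.

The SCORE2 model estimates 10-year risk of a first cardiovascular event
(cardiovascular death, non-fatal myocardial infarction or stroke) for
individuals aged 40-69 without prior CVD or diabetes, from six risk factors:
age, sex, current smoking, systolic blood pressure, total cholesterol and
HDL cholesterol. The model is a sex-specific proportional-hazards algorithm
with age-interaction terms, recalibrated to four European risk regions on
the complementary log-log scale.

Two clinical application modes are implemented:

* **calculator mode** — the unrounded algorithm, as implemented in online
  calculators: risk is a continuous fraction of the exact inputs.
* **chart mode** — the paper-chart reading: age is replaced by its 5-year
  bin midpoint, systolic blood pressure by its 20 mmHg bin midpoint, and
  the single cholesterol axis non-HDL (total minus HDL) by its 1 mmol/L bin
  midpoint; the resulting risk is rounded half-up to a whole percent.

Both modes share the same coefficient configuration (:class:`ModelSpec`),
loaded from a YAML file and validated for completeness.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "REGIONS",
    "SEXES",
    "COEFFICIENT_TERMS",
    "ConfigError",
    "RiskProfile",
    "ModelSpec",
    "ChartGrid",
    "RiskPair",
    "load_model_spec",
    "default_model_spec",
    "default_chart_grid",
    "round_half_up",
    "transform_covariates",
    "linear_predictor",
    "uncalibrated_risk",
    "recalibrate",
    "calculator_risk",
    "quantize_profile",
    "chart_risk",
    "render_chart",
    "calculator_risks",
    "chart_risks",
    "risk_pairs",
]

REGIONS = ("low", "moderate", "high", "very_high")
SEXES = ("male", "female")

#: transformed main-effect covariates and their age-interaction products,
#: in the order the linear predictor sums them
COEFFICIENT_TERMS = (
    "age",
    "smoking",
    "sbp",
    "tchol",
    "hdl",
    "smoking_x_age",
    "sbp_x_age",
    "tchol_x_age",
    "hdl_x_age",
)

_TRANSFORMED_COVARIATES = ("age", "sbp", "tchol", "hdl")


class ConfigError(ValueError):
    """Model configuration is incomplete or inconsistent."""


def round_half_up(x):
    """Round to the nearest integer, halves away from zero toward +inf.

    Chart cells print whole percents and a cell risk of 9.5% reads as 10%,
    so banker's rounding is not acceptable here.
    """
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)


@dataclass(frozen=True)
class RiskProfile:
    """One individual's SCORE2 inputs.

    age in years (decimals allowed), sbp in mmHg, cholesterol in mmol/L.
    """

    age: float
    sex: str
    smoker: bool
    sbp: float
    tchol: float
    hdl: float

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not (40.0 <= self.age < 70.0):
            raise ValueError(f"age {self.age} outside SCORE2 target range [40, 70)")
        if self.sbp <= 0:
            raise ValueError("sbp must be positive")
        if self.tchol <= 0 or self.hdl <= 0:
            raise ValueError("cholesterol values must be positive")
        if self.tchol <= self.hdl:
            raise ValueError("total cholesterol must exceed HDL cholesterol")

    @property
    def non_hdl(self) -> float:
        return self.tchol - self.hdl


@dataclass(frozen=True)
class ModelSpec:
    """Coefficients, transforms, baseline survival and recalibration scales.

    ``transforms`` maps each raw covariate to ``(center, divisor)``;
    ``coefficients`` maps sex to a dict over :data:`COEFFICIENT_TERMS`;
    ``baseline_survival`` maps sex to the 10-year baseline survival S0;
    ``scales`` maps ``(region, sex)`` to ``(scale1, scale2)``.
    """

    transforms: Mapping[str, tuple[float, float]]
    coefficients: Mapping[str, Mapping[str, float]]
    baseline_survival: Mapping[str, float]
    scales: Mapping[tuple[str, str], tuple[float, float]]

    def validate(self) -> "ModelSpec":
        for cov in _TRANSFORMED_COVARIATES:
            if cov not in self.transforms:
                raise ConfigError(f"missing transform constants for covariate {cov!r}")
            center, divisor = self.transforms[cov]
            if divisor == 0:
                raise ConfigError(f"zero transform divisor for covariate {cov!r}")
        for sex in SEXES:
            if sex not in self.coefficients:
                raise ConfigError(f"missing coefficients for sex {sex!r}")
            missing = set(COEFFICIENT_TERMS) - set(self.coefficients[sex])
            if missing:
                raise ConfigError(f"missing coefficient terms for {sex}: {sorted(missing)}")
            extra = set(self.coefficients[sex]) - set(COEFFICIENT_TERMS)
            if extra:
                raise ConfigError(f"unknown coefficient terms for {sex}: {sorted(extra)}")
            if sex not in self.baseline_survival:
                raise ConfigError(f"missing baseline survival for sex {sex!r}")
            s0 = self.baseline_survival[sex]
            if not (0.0 < s0 < 1.0):
                raise ConfigError(f"baseline survival for {sex} must be in (0,1), got {s0}")
        for region in REGIONS:
            for sex in SEXES:
                if (region, sex) not in self.scales:
                    raise ConfigError(f"missing recalibration scales for ({region}, {sex})")
                _, scale2 = self.scales[(region, sex)]
                if scale2 <= 0:
                    raise ConfigError(
                        f"scale2 must be positive for ({region}, {sex}), got {scale2}"
                    )
        return self


@dataclass(frozen=True)
class ChartGrid:
    """Half-open chart bins ``[lo, hi)`` for age, SBP and non-HDL cholesterol.

    Cell predictions use bin midpoints; values outside the grid are clamped
    to the boundary bins, as a clinician reading the edge row of a paper
    chart would do.
    """

    age_edges: tuple[float, ...] = (40, 45, 50, 55, 60, 65, 70)
    sbp_edges: tuple[float, ...] = (100, 120, 140, 160, 180)
    nonhdl_edges: tuple[float, ...] = (3, 4, 5, 6, 7)

    def __post_init__(self) -> None:
        for name, edges in (
            ("age", self.age_edges),
            ("sbp", self.sbp_edges),
            ("nonhdl", self.nonhdl_edges),
        ):
            if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
                raise ValueError(f"{name} bin edges must be strictly increasing")

    @staticmethod
    def _mids(edges: tuple[float, ...]) -> np.ndarray:
        e = np.asarray(edges, dtype=float)
        return (e[:-1] + e[1:]) / 2.0

    @property
    def age_midpoints(self) -> np.ndarray:
        return self._mids(self.age_edges)

    @property
    def sbp_midpoints(self) -> np.ndarray:
        return self._mids(self.sbp_edges)

    @property
    def nonhdl_midpoints(self) -> np.ndarray:
        return self._mids(self.nonhdl_edges)

    def _assign(self, values, edges, midpoints, name: str) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        idx = np.digitize(values, edges[1:-1], right=False)
        below = values < edges[0]
        above = values >= edges[-1]
        if np.any(below) or np.any(above):
            warnings.warn(
                f"{int(np.sum(below) + np.sum(above))} {name} value(s) outside the "
                f"chart range [{edges[0]}, {edges[-1]}) clamped to the boundary bin",
                stacklevel=3,
            )
        return np.asarray(midpoints)[idx]

    def assign_age(self, age) -> np.ndarray:
        return self._assign(age, self.age_edges, self.age_midpoints, "age")

    def assign_sbp(self, sbp) -> np.ndarray:
        return self._assign(sbp, self.sbp_edges, self.sbp_midpoints, "sbp")

    def assign_nonhdl(self, nonhdl) -> np.ndarray:
        return self._assign(nonhdl, self.nonhdl_edges, self.nonhdl_midpoints, "non-HDL")


@dataclass(frozen=True)
class RiskPair:
    """Per-individual calculator risk (fraction) and chart risk (integer %)."""

    calculator_risk: float
    chart_risk: int
    region: str


# ---------------------------------------------------------------------------
# configuration loading


def _spec_from_dict(cfg: dict) -> ModelSpec:
    try:
        transforms = {
            k: (float(v["center"]), float(v["divisor"]))
            for k, v in cfg["transforms"].items()
        }
        coefficients = {
            sex: {k: float(v) for k, v in terms.items()}
            for sex, terms in cfg["coefficients"].items()
        }
        baseline = {sex: float(v) for sex, v in cfg["baseline_survival"].items()}
        scales = {
            (region, sex): (float(sc["scale1"]), float(sc["scale2"]))
            for region, by_sex in cfg["recalibration"].items()
            for sex, sc in by_sex.items()
        }
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"malformed model configuration: missing key {exc}") from exc
    return ModelSpec(transforms, coefficients, baseline, scales).validate()


def _grid_from_dict(cfg: dict) -> ChartGrid:
    g = cfg.get("grid", {})
    kwargs = {}
    for key, attr in (
        ("age_edges", "age_edges"),
        ("sbp_edges", "sbp_edges"),
        ("nonhdl_edges", "nonhdl_edges"),
    ):
        if key in g:
            kwargs[attr] = tuple(float(x) for x in g[key])
    return ChartGrid(**kwargs)


def load_model_spec(path) -> tuple[ModelSpec, ChartGrid]:
    """Load and validate a model configuration YAML file.

    Returns the coefficient spec and the chart grid (grid section optional,
    defaults to the published layout).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return _spec_from_dict(cfg), _grid_from_dict(cfg)


def default_model_spec() -> ModelSpec:
    """The packaged SCORE2 coefficient set."""
    text = resources.files("score2modes.data").joinpath("score2_coefficients.yaml").read_text()
    return _spec_from_dict(yaml.safe_load(text))


def default_chart_grid() -> ChartGrid:
    text = resources.files("score2modes.data").joinpath("score2_coefficients.yaml").read_text()
    return _grid_from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# scalar operations (the algorithm, step by step)


def transform_covariates(profile: RiskProfile, spec: ModelSpec) -> dict[str, float]:
    """Center/scale the raw covariates and form the age-interaction products.

    Each continuous covariate x becomes (x - center)/divisor; smoking is the
    raw 0/1 indicator. The four interaction terms multiply the transformed
    covariate by transformed age.
    """
    out: dict[str, float] = {}
    for cov in _TRANSFORMED_COVARIATES:
        if cov not in spec.transforms:
            raise ConfigError(f"missing transform constants for covariate {cov!r}")
        center, divisor = spec.transforms[cov]
        out[cov] = (getattr(profile, cov) - center) / divisor
    out["smoking"] = 1.0 if profile.smoker else 0.0
    cage = out["age"]
    out["smoking_x_age"] = out["smoking"] * cage
    out["sbp_x_age"] = out["sbp"] * cage
    out["tchol_x_age"] = out["tchol"] * cage
    out["hdl_x_age"] = out["hdl"] * cage
    return out


def linear_predictor(covariates: Mapping[str, float], spec: ModelSpec, sex: str) -> float:
    """Sum of coefficient * transformed covariate over all nine terms."""
    if sex not in spec.coefficients:
        raise ConfigError(f"no coefficients for sex {sex!r}")
    coefs = spec.coefficients[sex]
    if set(coefs) != set(covariates):
        raise ConfigError(
            f"coefficient/covariate term mismatch: "
            f"{sorted(set(coefs) ^ set(covariates))}"
        )
    return float(sum(coefs[k] * covariates[k] for k in COEFFICIENT_TERMS))


def uncalibrated_risk(lp: float, spec: ModelSpec, sex: str) -> float:
    """10-year risk before regional recalibration: 1 - S0 ** exp(lp)."""
    s0 = spec.baseline_survival[sex]
    if not (0.0 < s0 < 1.0):
        raise ConfigError(f"baseline survival for {sex} must be in (0,1)")
    return float(1.0 - s0 ** math.exp(lp))


def recalibrate(risk_uncal: float, spec: ModelSpec, region: str, sex: str) -> float:
    """Map uncalibrated risk to the region's incidence level.

    Applied on the complementary log-log scale:
    1 - exp(-exp(scale1 + scale2 * ln(-ln(1 - risk)))). With scale2 > 0 the
    map is strictly increasing, so within-region risk ordering is preserved.
    """
    if not (0.0 < risk_uncal < 1.0):
        raise ValueError(f"risk must be in (0,1) to recalibrate, got {risk_uncal}")
    if (region, sex) not in spec.scales:
        raise ConfigError(f"missing recalibration scales for ({region}, {sex})")
    scale1, scale2 = spec.scales[(region, sex)]
    cll = math.log(-math.log(1.0 - risk_uncal))
    return float(1.0 - math.exp(-math.exp(scale1 + scale2 * cll)))


def calculator_risk(profile: RiskProfile, spec: ModelSpec, region: str) -> float:
    """Unrounded 10-year CVD risk (fraction), calculator mode."""
    cov = transform_covariates(profile, spec)
    lp = linear_predictor(cov, spec, profile.sex)
    return recalibrate(uncalibrated_risk(lp, spec, profile.sex), spec, region, profile.sex)


def quantize_profile(profile: RiskProfile, grid: ChartGrid | None = None) -> RiskProfile:
    """Replace age, SBP and cholesterol by their chart-cell midpoints.

    Non-HDL cholesterol (tchol - hdl) is computed first and binned on the
    chart's single cholesterol axis; the midpoint is re-expressed for the
    two-coefficient risk formula by pinning HDL at its centering constant
    (1.3 mmol/L in the published model) and setting
    tchol = midpoint non-HDL + that constant, which collapses the two
    cholesterol coefficients onto the chart's one axis.
    """
    grid = grid or ChartGrid()
    chart_age = float(grid.assign_age(profile.age))
    chart_sbp = float(grid.assign_sbp(profile.sbp))
    chart_nonhdl = float(grid.assign_nonhdl(profile.non_hdl))
    hdl_center = 1.3
    return replace(
        profile,
        age=chart_age,
        sbp=chart_sbp,
        tchol=chart_nonhdl + hdl_center,
        hdl=hdl_center,
    )


def chart_risk(
    profile: RiskProfile,
    spec: ModelSpec,
    region: str,
    grid: ChartGrid | None = None,
) -> int:
    """Chart-mode 10-year risk: whole percent, rounded half-up."""
    midpoint = quantize_profile(profile, grid)
    return int(round_half_up(100.0 * calculator_risk(midpoint, spec, region)))


def render_chart(
    spec: ModelSpec,
    region: str,
    sex: str,
    smoker: bool,
    grid: ChartGrid | None = None,
) -> pd.DataFrame:
    """One chart stratum (region, sex, smoking) as a long table.

    Columns: age_mid, sbp_mid, nonhdl_mid, risk_percent — one row per cell,
    each cell the rounded whole-percent risk at the cell midpoints.
    """
    grid = grid or ChartGrid()
    rows = []
    for age_mid in grid.age_midpoints:
        for sbp_mid in grid.sbp_midpoints:
            for nonhdl_mid in grid.nonhdl_midpoints:
                p = RiskProfile(
                    age=float(age_mid),
                    sex=sex,
                    smoker=smoker,
                    sbp=float(sbp_mid),
                    tchol=float(nonhdl_mid) + 1.3,
                    hdl=1.3,
                )
                rows.append(
                    {
                        "age_mid": float(age_mid),
                        "sbp_mid": float(sbp_mid),
                        "nonhdl_mid": float(nonhdl_mid),
                        "risk_percent": chart_risk(p, spec, region, grid),
                    }
                )
    return pd.DataFrame(rows)


def chart_text(table: pd.DataFrame) -> str:
    """Plain-text rendering of a chart stratum: one block per age bin,
    SBP bins as rows (high to low), non-HDL bins as columns."""
    lines: list[str] = []
    for age_mid, block in table.groupby("age_mid", sort=True):
        lines.append(f"age {age_mid:.1f}")
        pivot = block.pivot(index="sbp_mid", columns="nonhdl_mid", values="risk_percent")
        pivot = pivot.sort_index(ascending=False)
        header = "  sbp|nhdl " + " ".join(f"{c:>5.1f}" for c in pivot.columns)
        lines.append(header)
        for sbp_mid, row in pivot.iterrows():
            lines.append(f"  {sbp_mid:>9.0f} " + " ".join(f"{int(v):>5d}" for v in row))
        lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# vectorised cohort scoring

_REQUIRED_COLUMNS = ("age", "sex", "smoker", "sbp", "tchol", "hdl", "region")


def _check_cohort_frame(df: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort frame missing columns: {missing}")


def _risks_from_arrays(
    age: np.ndarray,
    smoker: np.ndarray,
    sbp: np.ndarray,
    tchol: np.ndarray,
    hdl: np.ndarray,
    sex: np.ndarray,
    region: np.ndarray,
    spec: ModelSpec,
) -> np.ndarray:
    out = np.empty(age.shape, dtype=float)
    c_age, d_age = spec.transforms["age"]
    c_sbp, d_sbp = spec.transforms["sbp"]
    c_tc, d_tc = spec.transforms["tchol"]
    c_hdl, d_hdl = spec.transforms["hdl"]
    za = (age - c_age) / d_age
    zb = (sbp - c_sbp) / d_sbp
    zt = (tchol - c_tc) / d_tc
    zh = (hdl - c_hdl) / d_hdl
    zs = smoker.astype(float)
    for sx in SEXES:
        mask_sex = sex == sx
        if not np.any(mask_sex):
            continue
        b = spec.coefficients[sx]
        lp = (
            b["age"] * za
            + b["smoking"] * zs
            + b["sbp"] * zb
            + b["tchol"] * zt
            + b["hdl"] * zh
            + b["smoking_x_age"] * zs * za
            + b["sbp_x_age"] * zb * za
            + b["tchol_x_age"] * zt * za
            + b["hdl_x_age"] * zh * za
        )
        s0 = spec.baseline_survival[sx]
        uncal = 1.0 - s0 ** np.exp(lp)
        cll = np.log(-np.log1p(-uncal))
        for reg in np.unique(region[mask_sex]):
            if (reg, sx) not in spec.scales:
                raise ConfigError(f"missing recalibration scales for ({reg}, {sx})")
            scale1, scale2 = spec.scales[(reg, sx)]
            m = mask_sex & (region == reg)
            out[m] = 1.0 - np.exp(-np.exp(scale1 + scale2 * cll[m]))
    return out


def calculator_risks(df: pd.DataFrame, spec: ModelSpec | None = None) -> np.ndarray:
    """Calculator-mode risks (fractions) for a cohort frame.

    Expects columns age, sex ('male'/'female'), smoker (bool/0-1), sbp,
    tchol, hdl, region.
    """
    spec = spec or default_model_spec()
    _check_cohort_frame(df)
    return _risks_from_arrays(
        df["age"].to_numpy(dtype=float),
        df["smoker"].to_numpy(),
        df["sbp"].to_numpy(dtype=float),
        df["tchol"].to_numpy(dtype=float),
        df["hdl"].to_numpy(dtype=float),
        df["sex"].to_numpy(),
        df["region"].to_numpy(),
        spec,
    )


def chart_risks(
    df: pd.DataFrame,
    spec: ModelSpec | None = None,
    grid: ChartGrid | None = None,
) -> np.ndarray:
    """Chart-mode risks (integer percents) for a cohort frame."""
    spec = spec or default_model_spec()
    grid = grid or ChartGrid()
    _check_cohort_frame(df)
    age_mid = grid.assign_age(df["age"].to_numpy(dtype=float))
    sbp_mid = grid.assign_sbp(df["sbp"].to_numpy(dtype=float))
    nonhdl = df["tchol"].to_numpy(dtype=float) - df["hdl"].to_numpy(dtype=float)
    nonhdl_mid = grid.assign_nonhdl(nonhdl)
    hdl_center = np.full(len(df), 1.3)
    risk = _risks_from_arrays(
        age_mid,
        df["smoker"].to_numpy(),
        sbp_mid,
        nonhdl_mid + 1.3,
        hdl_center,
        df["sex"].to_numpy(),
        df["region"].to_numpy(),
        spec,
    )
    return round_half_up(100.0 * risk)


def risk_pairs(
    df: pd.DataFrame,
    spec: ModelSpec | None = None,
    grid: ChartGrid | None = None,
) -> pd.DataFrame:
    """Both modes for a cohort frame.

    Returns a frame aligned with ``df`` with columns ``calculator_risk``
    (fraction) and ``chart_risk`` (integer percent).
    """
    spec = spec or default_model_spec()
    return pd.DataFrame(
        {
            "calculator_risk": calculator_risks(df, spec),
            "chart_risk": chart_risks(df, spec, grid),
        },
        index=df.index,
    )
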