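"""One reproducible run: simulate/load -> score -> validate -> impact.

`run` orchestrates the full comparison of the two application modes on one
or more cohort groups (simulated presets, or region groups of a supplied
cohort file) and writes delimited-text reports mirroring the shape of a
published model-comparison: cohort characteristics, discrimination by sex
and overall, calibration per mode, reclassification, net benefit,
eligibility overlap, and the treatment-impact table, plus one
machine-readable JSON summary.

A single master seed fans out to per-stage child seeds through
``numpy.random.SeedSequence.spawn``, so each stage is independently
reproducible and two runs with the same configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import impact as impact_mod
from .engine import (
    ChartGrid,
    ModelSpec,
    default_chart_grid,
    default_model_spec,
    load_model_spec,
    risk_pairs,
)
from .simulate import COHORT_COLUMNS, PopulationParams, preset_populations, simulate_cohort
from .validation import (
    SurvivalSample,
    c_index_difference,
    calibration_by_decile,
    categorical_nri,
    harrell_c_competing,
    net_benefit,
    net_benefit_curve,
)

__all__ = ["RunConfig", "run", "read_cohort", "write_cohort", "SchemaError"]

_FLOAT_FMT = "%.6g"


class SchemaError(ValueError):
    """A cohort file violates the strict column schema."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one input mode: ``presets`` (simulate the named preset
    populations) or ``cohort_path`` (load a delimited cohort file and group
    rows by risk region, pooling high with very_high as in mixed
    Eastern-European cohorts).
    """

    output_dir: str
    seed: int = 0
    presets: tuple[str, ...] | None = ("low_region", "high_region")
    cohort_path: str | None = None
    model_config: str | None = None
    n_override: int | None = None
    horizon: float = 10.0
    hr: float = 0.5
    hr_scale: str = "hazard"
    thresholds: tuple[float, float] = (0.05, 0.10)
    net_benefit_pt: float = 0.10
    n_boot: int = 200

    def __post_init__(self) -> None:
        if (self.presets is None) == (self.cohort_path is None):
            raise ValueError("exactly one of presets / cohort_path must be given")
        if self.cohort_path is not None and not Path(self.cohort_path).exists():
            raise FileNotFoundError(self.cohort_path)
        if self.model_config is not None and not Path(self.model_config).exists():
            raise FileNotFoundError(self.model_config)


# ---------------------------------------------------------------------------
# cohort file I/O (strict schema)

_SEX_CODES = {"M": "male", "F": "female"}
_SEX_CODES_OUT = {"male": "M", "female": "F"}
_VALID_REGIONS = {"low", "moderate", "high", "very_high"}


def read_cohort(path) -> pd.DataFrame:
    """Read a delimited cohort file with the strict pipeline schema.

    Columns: id, age, sex (M/F), smoker (0/1), sbp, tchol, hdl, region,
    time, event (0/1/2) and optionally true_risk. Any violation raises
    :class:`SchemaError` naming the row and column.
    """
    df = pd.read_csv(path, sep="\t")
    required = [c for c in COHORT_COLUMNS if c != "true_risk"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file missing columns: {missing}")

    def _bad(mask, column, reason):
        if mask.any():
            row = int(np.argmax(mask.to_numpy()))
            raise SchemaError(f"row {row}, column {column!r}: {reason}")

    _bad(~df["sex"].isin(_SEX_CODES), "sex", "must be 'M' or 'F'")
    _bad(~df["event"].isin((0, 1, 2)), "event", "must be 0, 1 or 2")
    _bad(~df["region"].isin(_VALID_REGIONS), "region", f"must be one of {sorted(_VALID_REGIONS)}")
    _bad(~df["smoker"].isin((0, 1, True, False)), "smoker", "must be 0 or 1")
    for col in ("age", "sbp", "tchol", "hdl", "time"):
        vals = pd.to_numeric(df[col], errors="coerce")
        _bad(vals.isna(), col, "must be numeric")
        df[col] = vals
    _bad(df["time"] <= 0, "time", "must be positive")
    _bad((df["age"] < 40) | (df["age"] >= 70), "age", "must be in [40, 70)")
    out = df.copy()
    out["sex"] = out["sex"].map(_SEX_CODES)
    out["smoker"] = out["smoker"].astype(bool)
    out["event"] = out["event"].astype(int)
    return out


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort frame in the pipeline's delimited-text schema."""
    out = df.copy()
    out["sex"] = out["sex"].map(_SEX_CODES_OUT)
    out["smoker"] = out["smoker"].astype(int)
    cols = [c for c in COHORT_COLUMNS if c in out.columns]
    cols += [c for c in out.columns if c not in cols]
    out[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# run


def _characteristics(df: pd.DataFrame) -> pd.DataFrame:
    q = df[["tchol", "hdl"]].quantile([0.25, 0.5, 0.75])
    return pd.DataFrame(
        [
            ("n", len(df)),
            ("male_pct", 100.0 * (df["sex"] == "male").mean()),
            ("age_mean", df["age"].mean()),
            ("age_sd", df["age"].std()),
            ("smoker_pct", 100.0 * df["smoker"].mean()),
            ("sbp_mean", df["sbp"].mean()),
            ("sbp_sd", df["sbp"].std()),
            ("tchol_median", q.loc[0.5, "tchol"]),
            ("tchol_q1", q.loc[0.25, "tchol"]),
            ("tchol_q3", q.loc[0.75, "tchol"]),
            ("hdl_median", q.loc[0.5, "hdl"]),
            ("hdl_q1", q.loc[0.25, "hdl"]),
            ("hdl_q3", q.loc[0.75, "hdl"]),
            ("followup_median", df["time"].median()),
            ("cvd_events", int((df["event"] == 1).sum())),
            ("noncvd_deaths", int((df["event"] == 2).sum())),
        ],
        columns=["statistic", "value"],
    )


def _discrimination(
    df: pd.DataFrame, pairs: pd.DataFrame, horizon: float, n_boot: int, seed: int
) -> pd.DataFrame:
    rows = []
    strata = [("overall", np.ones(len(df), dtype=bool))]
    strata += [(sx, (df["sex"] == sx).to_numpy()) for sx in ("male", "female")]
    for label, mask in strata:
        try:
            calc = SurvivalSample(
                pairs["calculator_risk"].to_numpy()[mask],
                df["time"].to_numpy()[mask],
                df["event"].to_numpy()[mask],
            )
            chart = SurvivalSample(
                pairs["chart_risk"].to_numpy()[mask] / 100.0,
                df["time"].to_numpy()[mask],
                df["event"].to_numpy()[mask],
            )
            res = c_index_difference(calc, chart, n_boot=n_boot, seed=seed)
        except ValueError as exc:
            import warnings as _warnings

            _warnings.warn(f"discrimination undefined for stratum {label!r}: {exc}")
            res = {"c_a": np.nan, "c_b": np.nan, "delta_c": np.nan,
                   "ci": (np.nan, np.nan)}
        rows.append(
            {
                "stratum": label,
                "c_calculator": res["c_a"],
                "c_chart": res["c_b"],
                "delta_c": res["delta_c"],
                "delta_c_ci_low": res["ci"][0],
                "delta_c_ci_high": res["ci"][1],
            }
        )
    return pd.DataFrame(rows)


def _load_groups(config: RunConfig, spec: ModelSpec, seed_root: np.random.SeedSequence):
    groups: list[tuple[str, pd.DataFrame]] = []
    if config.presets is not None:
        presets = preset_populations()
        children = seed_root.spawn(len(config.presets))
        for name, child in zip(config.presets, children):
            if name not in presets:
                raise ValueError(f"unknown preset {name!r}; have {sorted(presets)}")
            params = presets[name]
            if config.n_override is not None:
                params = dataclasses.replace(params, n=config.n_override)
            child_seed = int(child.generate_state(1)[0] % 2**31)
            groups.append((name, simulate_cohort(params, child_seed, spec, config.horizon)))
    else:
        df = read_cohort(config.cohort_path)
        pooled = df["region"].map(
            {"low": "low", "moderate": "moderate", "high": "high_very_high",
             "very_high": "high_very_high"}
        )
        for name in pd.unique(pooled):
            groups.append((str(name), df[pooled == name].reset_index(drop=True)))
    return groups


def run(config: RunConfig) -> dict:
    """Execute the full comparison; returns the JSON-style summary dict.

    Writes, per cohort group: characteristics, scored cohort, discrimination
    (overall and by sex), calibration per mode, NRI, net benefit (at the
    configured threshold plus a sweep), eligibility overlap, and the
    treatment-impact table; plus ``summary.json`` covering all groups.
    All tables are computed before anything is written, so a failure leaves
    no partial report files.
    """
    if config.model_config is not None:
        spec, grid = load_model_spec(config.model_config)
    else:
        spec, grid = default_model_spec(), default_chart_grid()

    seed_root = np.random.SeedSequence(config.seed)
    sim_seq, boot_seq = seed_root.spawn(2)
    groups = _load_groups(config, spec, sim_seq)

    outputs: dict[str, pd.DataFrame] = {}
    summary: dict = {
        "seed": config.seed,
        "horizon": config.horizon,
        "hazard_ratio": config.hr,
        "hr_scale": config.hr_scale,
        "thresholds": list(config.thresholds),
        "net_benefit_pt": config.net_benefit_pt,
        "n_boot": config.n_boot,
        "groups": {},
    }

    boot_children = boot_seq.spawn(len(groups))
    for (name, df), boot_child in zip(groups, boot_children):
        bseed = int(boot_child.generate_state(1)[0] % 2**31)
        pairs = risk_pairs(df, spec, grid)
        scored = df.copy()
        scored["calculator_risk"] = pairs["calculator_risk"]
        scored["chart_risk"] = pairs["chart_risk"]

        time = df["time"].to_numpy()
        event = df["event"].to_numpy()
        calc = SurvivalSample(pairs["calculator_risk"].to_numpy(), time, event)
        chart = SurvivalSample(pairs["chart_risk"].to_numpy() / 100.0, time, event)

        disc = _discrimination(df, pairs, config.horizon, config.n_boot, bseed)
        import warnings as _warnings

        empty_cal = pd.DataFrame(
            columns=["group", "n", "mean_predicted", "observed_cif", "ci_low", "ci_high"]
        )
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # chart-mode integer ties are expected
            try:
                cal_calc = calibration_by_decile(calc, config.horizon)
                cal_chart = calibration_by_decile(chart, config.horizon)
            except ValueError:
                cal_calc = cal_chart = empty_cal
            nri = categorical_nri(
                calc, chart, config.thresholds, config.horizon, config.n_boot, bseed
            )
        nb_calc = net_benefit(calc, config.net_benefit_pt, config.horizon)
        nb_chart = net_benefit(chart, config.net_benefit_pt, config.horizon)
        nb_table = pd.DataFrame(
            [
                {"method": "calculator", "pt": nb_calc.threshold, "weight": nb_calc.weight,
                 "net_benefit": nb_calc.net_benefit, "per_1000": nb_calc.net_benefit_per_1000,
                 "tp_rate": nb_calc.tp_rate, "fp_rate": nb_calc.fp_rate},
                {"method": "chart", "pt": nb_chart.threshold, "weight": nb_chart.weight,
                 "net_benefit": nb_chart.net_benefit, "per_1000": nb_chart.net_benefit_per_1000,
                 "tp_rate": nb_chart.tp_rate, "fp_rate": nb_chart.fp_rate},
            ]
        )
        nb_curve_calc = net_benefit_curve(calc, horizon=config.horizon)
        nb_curve_calc.insert(0, "method", "calculator")
        nb_curve_chart = net_benefit_curve(chart, horizon=config.horizon)
        nb_curve_chart.insert(0, "method", "chart")
        nb_curve = pd.concat([nb_curve_calc, nb_curve_chart], ignore_index=True)

        elig_calc = impact_mod.classify_cohort(
            df["age"].to_numpy(), pairs["calculator_risk"].to_numpy(),
            pairs["chart_risk"].to_numpy(), "calculator",
        )
        elig_chart = impact_mod.classify_cohort(
            df["age"].to_numpy(), pairs["calculator_risk"].to_numpy(),
            pairs["chart_risk"].to_numpy(), "chart",
        )
        overlap = impact_mod.eligibility_overlap(
            elig_calc, elig_chart, time, event, config.horizon
        )
        imp = impact_mod.impact_report(
            df, pairs, config.hr, config.horizon, config.hr_scale, group_label=name
        )

        nri_table = pd.DataFrame(
            [
                {"component": "events", "nri": nri.nri_events,
                 "ci_low": nri.ci_events[0] if nri.ci_events else np.nan,
                 "ci_high": nri.ci_events[1] if nri.ci_events else np.nan},
                {"component": "nonevents", "nri": nri.nri_nonevents,
                 "ci_low": nri.ci_nonevents[0] if nri.ci_nonevents else np.nan,
                 "ci_high": nri.ci_nonevents[1] if nri.ci_nonevents else np.nan},
                {"component": "overall", "nri": nri.nri_overall,
                 "ci_low": nri.ci_overall[0] if nri.ci_overall else np.nan,
                 "ci_high": nri.ci_overall[1] if nri.ci_overall else np.nan},
            ]
        )

        outputs[f"{name}_characteristics.tsv"] = _characteristics(df)
        outputs[f"{name}_cohort_scored.tsv"] = scored
        outputs[f"{name}_discrimination.tsv"] = disc
        outputs[f"{name}_calibration_calculator.tsv"] = cal_calc
        outputs[f"{name}_calibration_chart.tsv"] = cal_chart
        outputs[f"{name}_nri.tsv"] = nri_table
        outputs[f"{name}_net_benefit.tsv"] = nb_table
        outputs[f"{name}_net_benefit_curve.tsv"] = nb_curve
        outputs[f"{name}_eligibility_overlap.tsv"] = overlap
        outputs[f"{name}_impact.tsv"] = imp

        summary["groups"][name] = {
            "n": len(df),
            "median_calculator_pct": float(np.median(100 * pairs["calculator_risk"])),
            "median_chart_pct": float(np.median(pairs["chart_risk"])),
            "c_calculator": float(disc.loc[disc.stratum == "overall", "c_calculator"].iloc[0]),
            "c_chart": float(disc.loc[disc.stratum == "overall", "c_chart"].iloc[0]),
            "delta_c": float(disc.loc[disc.stratum == "overall", "delta_c"].iloc[0]),
            "nri_overall": nri.nri_overall,
            "net_benefit_calculator_per_1000": nb_calc.net_benefit_per_1000,
            "net_benefit_chart_per_1000": nb_chart.net_benefit_per_1000,
            "pct_eligible_calculator": float(
                imp.loc[imp.method == "calculator", "pct_eligible"].iloc[0]
            ),
            "pct_eligible_chart": float(imp.loc[imp.method == "chart", "pct_eligible"].iloc[0]),
            "per_1000_prevented_calculator": int(
                imp.loc[imp.method == "calculator", "per_1000_treated"].iloc[0]
            ),
            "per_1000_prevented_chart": int(
                imp.loc[imp.method == "chart", "per_1000_treated"].iloc[0]
            ),
        }

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    for fname, table in outputs.items():
        if fname.endswith("_cohort_scored.tsv"):
            tmp = table.copy()
            tmp["sex"] = tmp["sex"].map(_SEX_CODES_OUT)
            tmp["smoker"] = tmp["smoker"].astype(int)
            tmp.to_csv(outdir / fname, sep="\t", index=False, float_format="%.10g")
        else:
            table.to_csv(outdir / fname, sep="\t", index=False, float_format=_FLOAT_FMT)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
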