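"""Risk-engine unit and property tests: transforms, linear predictor,
baseline risk, recalibration, both application modes, chart rendering."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from score2modes.engine import (
    ChartGrid,
    ConfigError,
    ModelSpec,
    RiskProfile,
    calculator_risk,
    calculator_risks,
    chart_risk,
    chart_risks,
    linear_predictor,
    load_model_spec,
    quantize_profile,
    recalibrate,
    render_chart,
    round_half_up,
    transform_covariates,
    uncalibrated_risk,
)

REFERENCE = dict(age=60.0, sex="male", smoker=False, sbp=120.0, tchol=6.0, hdl=1.3)


def make_profile(**kw):
    return RiskProfile(**{**REFERENCE, **kw})


def _profile_from(age, sex, smoker, sbp, hdl, nonhdl):
    return make_profile(age=age, sex=sex, smoker=smoker, sbp=sbp, hdl=hdl, tchol=hdl + nonhdl)


profiles = st.builds(
    _profile_from,
    age=st.floats(40, 69.99),
    sex=st.sampled_from(["male", "female"]),
    smoker=st.booleans(),
    sbp=st.floats(90, 200),
    hdl=st.floats(0.7, 2.4),
    nonhdl=st.floats(1.5, 7.5),
)


class TestTransforms:
    def test_centering_identity(self, spec):
        cov = transform_covariates(make_profile(), spec)
        assert all(v == 0.0 for v in cov.values())

    def test_unit_step_in_age(self, spec):
        cov = transform_covariates(make_profile(age=65.0), spec)
        assert cov["age"] == pytest.approx(1.0)

    def test_hand_computed_vector(self, spec):
        # spreadsheet-style arithmetic: each (x - center) / divisor
        p = make_profile(age=55.0, smoker=True, sbp=140.0, tchol=6.3, hdl=1.1)
        cov = transform_covariates(p, spec)
        assert cov["age"] == pytest.approx((55 - 60) / 5)
        assert cov["sbp"] == pytest.approx((140 - 120) / 20)
        assert cov["tchol"] == pytest.approx(6.3 - 6.0)
        assert cov["hdl"] == pytest.approx((1.1 - 1.3) / 0.5)
        assert cov["smoking"] == 1.0
        assert cov["smoking_x_age"] == pytest.approx(-1.0)
        assert cov["sbp_x_age"] == pytest.approx(1.0 * -1.0)
        assert cov["tchol_x_age"] == pytest.approx(0.3 * -1.0, rel=1e-12)
        assert cov["hdl_x_age"] == pytest.approx(-0.4 * -1.0, rel=1e-12)

    def test_missing_transform_is_config_error(self, spec):
        broken = ModelSpec(
            transforms={k: v for k, v in spec.transforms.items() if k != "hdl"},
            coefficients=spec.coefficients,
            baseline_survival=spec.baseline_survival,
            scales=spec.scales,
        )
        with pytest.raises(ConfigError, match="hdl"):
            transform_covariates(make_profile(), broken)


class TestLinearPredictor:
    def test_zero_vector_gives_zero(self, spec):
        cov = transform_covariates(make_profile(), spec)
        assert linear_predictor(cov, spec, "male") == 0.0

    def test_single_term_linearity(self, spec):
        cov = transform_covariates(make_profile(sbp=140.0), spec)
        expected = spec.coefficients["female"]["sbp"] * 1.0
        assert linear_predictor(cov, spec, "female") == pytest.approx(expected)

    def test_matches_dot_product_oracle(self, spec):
        p = make_profile(age=47.0, smoker=True, sbp=152.0, tchol=5.1, hdl=1.6)
        cov = transform_covariates(p, spec)
        oracle = sum(spec.coefficients["male"][k] * cov[k] for k in cov)
        assert linear_predictor(cov, spec, "male") == pytest.approx(oracle, rel=1e-14)

    def test_term_mismatch_is_config_error(self, spec):
        cov = transform_covariates(make_profile(), spec)
        cov.pop("hdl_x_age")
        with pytest.raises(ConfigError, match="mismatch"):
            linear_predictor(cov, spec, "male")


class TestBaselineAndRecalibration:
    def test_lp_zero_gives_one_minus_s0(self, spec):
        for sex in ("male", "female"):
            s0 = spec.baseline_survival[sex]
            assert uncalibrated_risk(0.0, spec, sex) == pytest.approx(1.0 - s0)

    def test_extreme_lp_limits(self, spec):
        assert uncalibrated_risk(-20.0, spec, "male") == pytest.approx(0.0, abs=1e-6)
        assert uncalibrated_risk(20.0, spec, "male") == pytest.approx(1.0, abs=1e-6)

    def test_direct_evaluation(self):
        # 1 - 0.96 ** exp(0.5), evaluated independently
        spec = ModelSpec(
            transforms={}, coefficients={}, baseline_survival={"male": 0.96}, scales={}
        )
        assert uncalibrated_risk(0.5, spec, "male") == pytest.approx(
            0.06508913957111151, abs=1e-12
        )

    def _spec_with_scales(self, spec, s1, s2):
        return ModelSpec(
            transforms=spec.transforms,
            coefficients=spec.coefficients,
            baseline_survival=spec.baseline_survival,
            scales={("low", "male"): (s1, s2)},
        )

    def test_identity_scales(self, spec):
        s = self._spec_with_scales(spec, 0.0, 1.0)
        for r in (0.01, 0.10, 0.42, 0.90):
            assert recalibrate(r, s, "low", "male") == pytest.approx(r, abs=1e-12)

    def test_closed_form_value(self, spec):
        s = self._spec_with_scales(spec, -0.57, 0.75)
        assert recalibrate(0.10, s, "low", "male") == pytest.approx(
            0.09929984783884171, abs=1e-12
        )

    def test_domain_error(self, spec):
        with pytest.raises(ValueError):
            recalibrate(0.0, spec, "low", "male")
        with pytest.raises(ValueError):
            recalibrate(1.0, spec, "low", "male")

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        ra=st.floats(1e-6, 0.999),
        rb=st.floats(1e-6, 0.999),
        s1=st.floats(-2, 2),
        s2=st.floats(0.05, 3),
    )
    def test_rank_preservation_property(self, spec, ra, rb, s1, s2):
        if abs(ra - rb) < 1e-9:
            return
        s = self._spec_with_scales(spec, s1, s2)
        lo, hi = sorted((ra, rb))
        assert recalibrate(lo, s, "low", "male") < recalibrate(hi, s, "low", "male")


class TestCalculatorRisk:
    def test_separate_cholesterol_coefficients(self, spec):
        # same non-HDL (4.5), different TC/HDL splits -> different risks
        a = make_profile(tchol=6.0, hdl=1.5)
        b = make_profile(tchol=5.5, hdl=1.0)
        ra = calculator_risk(a, spec, "low")
        rb = calculator_risk(b, spec, "low")
        assert ra != pytest.approx(rb, abs=1e-6)

    def test_reference_profile_composition(self, spec):
        for region in ("low", "moderate", "high", "very_high"):
            expected = recalibrate(
                1.0 - spec.baseline_survival["male"], spec, region, "male"
            )
            assert calculator_risk(make_profile(), spec, region) == pytest.approx(expected)

    def test_end_to_end_chained_arithmetic(self, spec):
        p = make_profile(age=50.0, sex="male", smoker=True, sbp=140.0, tchol=6.3, hdl=1.4)
        b = spec.coefficients["male"]
        za, zs, zb_, zt, zh = -2.0, 1.0, 1.0, 0.3, 0.2
        lp = (
            b["age"] * za + b["smoking"] * zs + b["sbp"] * zb_ + b["tchol"] * zt
            + b["hdl"] * zh + b["smoking_x_age"] * zs * za + b["sbp_x_age"] * zb_ * za
            + b["tchol_x_age"] * zt * za + b["hdl_x_age"] * zh * za
        )
        uncal = 1.0 - spec.baseline_survival["male"] ** math.exp(lp)
        s1, s2 = spec.scales[("low", "male")]
        expected = 1.0 - math.exp(-math.exp(s1 + s2 * math.log(-math.log(1 - uncal))))
        assert calculator_risk(p, spec, "low") == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(delta=st.floats(0.5, 30))
    def test_monotone_in_sbp_at_age_center(self, spec, delta):
        lo = calculator_risk(make_profile(sbp=120.0), spec, "low")
        hi = calculator_risk(make_profile(sbp=120.0 + delta), spec, "low")
        assert hi > lo

    def test_monotone_directions_at_age_center(self, spec):
        base = calculator_risk(make_profile(), spec, "moderate")
        assert calculator_risk(make_profile(tchol=7.0), spec, "moderate") > base
        assert calculator_risk(make_profile(hdl=1.8), spec, "moderate") < base

    def test_vectorised_matches_scalar(self, spec):
        rows = [
            dict(age=44, sex="female", smoker=True, sbp=128, tchol=4.9, hdl=1.2, region="low"),
            dict(age=61, sex="male", smoker=False, sbp=163, tchol=6.8, hdl=0.9, region="high"),
            dict(age=55, sex="male", smoker=True, sbp=101, tchol=5.0, hdl=1.4, region="very_high"),
        ]
        df = pd.DataFrame(rows)
        vec = calculator_risks(df, spec)
        for i, row in enumerate(rows):
            region = row.pop("region")
            assert vec[i] == pytest.approx(
                calculator_risk(RiskProfile(**row), spec, region), rel=1e-12
            )


class TestQuantization:
    def test_age_63_maps_to_62_5(self, grid):
        q = quantize_profile(make_profile(age=63.0), grid)
        assert q.age == 62.5

    def test_shared_nonhdl_cell(self, grid):
        qa = quantize_profile(make_profile(tchol=6.0, hdl=1.5), grid)
        qb = quantize_profile(make_profile(tchol=5.5, hdl=1.0), grid)
        assert qa.non_hdl == pytest.approx(4.5)
        assert (qa.tchol, qa.hdl) == (qb.tchol, qb.hdl)

    def test_bin_edge_goes_to_upper_bin(self, grid):
        assert quantize_profile(make_profile(age=65.0), grid).age == 67.5
        assert quantize_profile(make_profile(sbp=140.0), grid).sbp == 150.0

    def test_out_of_grid_clamped_with_warning(self, grid):
        with pytest.warns(UserWarning, match="clamped"):
            q = quantize_profile(make_profile(sbp=210.0), grid)
        assert q.sbp == 170.0
        with pytest.warns(UserWarning, match="clamped"):
            q = quantize_profile(make_profile(tchol=3.0, hdl=1.0), grid)
        assert q.non_hdl == pytest.approx(3.5)

    def test_sex_and_smoking_untouched(self, grid):
        q = quantize_profile(make_profile(sex="female", smoker=True, age=48.0), grid)
        assert q.sex == "female" and q.smoker is True


class TestChartRisk:
    def test_round_half_up_anchors(self):
        assert round_half_up(9.5) == 10
        assert round_half_up(9.49) == 9
        assert round_half_up(np.array([0.4, 0.5, 1.5, 2.49])).tolist() == [0, 1, 2, 2]

    def test_quantization_fixed_point(self, spec, grid):
        p = make_profile(age=62.5, sbp=130.0, tchol=4.5 + 1.3, hdl=1.3)
        expected = int(round_half_up(100 * calculator_risk(p, spec, "low")))
        assert chart_risk(p, spec, "low", grid) == expected

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(p=profiles)
    def test_chart_equals_rounded_midpoint_risk(self, spec, grid, p):
        q = quantize_profile(p, grid)
        expected = int(round_half_up(100 * calculator_risk(q, spec, "moderate")))
        assert chart_risk(p, spec, "moderate", grid) == expected

    def test_vectorised_matches_scalar(self, spec, grid):
        df = pd.DataFrame(
            [
                dict(age=63, sex="male", smoker=True, sbp=145, tchol=6.0, hdl=1.5, region="low"),
                dict(age=41, sex="female", smoker=False, sbp=118, tchol=5.0, hdl=1.1, region="high"),
            ]
        )
        vec = chart_risks(df, spec, grid)
        for i, row in df.iterrows():
            p = RiskProfile(row.age, row.sex, bool(row.smoker), row.sbp, row.tchol, row.hdl)
            assert vec[i] == chart_risk(p, spec, row.region, grid)


class TestRenderChart:
    def test_cells_match_per_cell_calls(self, spec):
        mini = ChartGrid(age_edges=(55, 60, 65), sbp_edges=(120, 140, 160), nonhdl_edges=(4, 5, 6))
        table = render_chart(spec, "moderate", "female", True, mini)
        assert len(table) == 8
        for _, row in table.iterrows():
            p = RiskProfile(row.age_mid, "female", True, row.sbp_mid, row.nonhdl_mid + 1.3, 1.3)
            assert row.risk_percent == chart_risk(p, spec, "moderate", mini)

    def test_deterministic(self, spec, grid):
        t1 = render_chart(spec, "low", "male", False, grid)
        t2 = render_chart(spec, "low", "male", False, grid)
        pd.testing.assert_frame_equal(t1, t2)

    def test_monotone_in_age(self, spec, grid):
        table = render_chart(spec, "high", "male", True, grid)
        for _, block in table.groupby(["sbp_mid", "nonhdl_mid"]):
            vals = block.sort_values("age_mid")["risk_percent"].to_numpy()
            assert np.all(np.diff(vals) >= 0)


class TestConfig:
    def test_profile_invariants(self):
        with pytest.raises(ValueError):
            make_profile(age=39.0)
        with pytest.raises(ValueError):
            make_profile(age=70.0)
        with pytest.raises(ValueError):
            make_profile(tchol=1.0, hdl=1.2)

    def test_incomplete_config_rejected(self, tmp_path, spec):
        import yaml

        cfg = {
            "transforms": {k: {"center": c, "divisor": d} for k, (c, d) in spec.transforms.items()},
            "coefficients": {"male": dict(spec.coefficients["male"])},  # female missing
            "baseline_survival": dict(spec.baseline_survival),
            "recalibration": {
                region: {
                    sex: {"scale1": spec.scales[(region, sex)][0],
                          "scale2": spec.scales[(region, sex)][1]}
                    for sex in ("male", "female")
                }
                for region in ("low", "moderate", "high", "very_high")
            },
        }
        path = tmp_path / "broken.yaml"
        path.write_text(yaml.safe_dump(cfg))
        with pytest.raises(ConfigError, match="female"):
            load_model_spec(path)

    def test_nonpositive_scale2_rejected(self, spec):
        bad_scales = dict(spec.scales)
        bad_scales[("low", "male")] = (0.1, -1.0)
        with pytest.raises(ConfigError, match="scale2"):
            ModelSpec(
                spec.transforms, spec.coefficients, spec.baseline_survival, bad_scales
            ).validate()
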