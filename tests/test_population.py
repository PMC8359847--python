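"""Unit and property tests for the virtual-population generator."""

import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

import geripbpk as g
from geripbpk.population import (
    AgeDistribution,
    calibrate_weibull_scale,
    normalize_sex,
    subject_streams,
)


class TestAgeSampling:
    def test_band_share_matches_survey_proportion(self, default_spec, rng):
        ages = g.sample_age(default_spec, 4000, rng)
        # survey: 5613 of 7077 subjects in the 65-75 band
        assert np.mean(ages <= 75) == pytest.approx(0.79, abs=0.02)

    def test_degenerate_truncation_returns_constant(self, rng):
        spec = g.PopulationSpec(age_min=70, age_max=70)
        assert np.all(g.sample_age(spec, 50, rng) == 70.0)

    def test_truncation_bounds(self, default_spec, rng):
        ages = g.sample_age(default_spec, 100_000, rng)
        assert ages.min() >= 65.0 and ages.max() <= default_spec.age_max

    def test_invalid_inputs(self, default_spec, rng):
        with pytest.raises(ValueError):
            g.sample_age(default_spec, 0, rng)
        with pytest.raises(ValidationError):
            AgeDistribution(shape=-1.0)
        with pytest.raises(ValidationError):
            AgeDistribution(scale=0.0)

    def test_scale_calibration_reproduces_default(self, default_spec):
        scale = calibrate_weibull_scale()
        assert scale == pytest.approx(default_spec.age_dist.scale, abs=1e-6)


class TestHeight:
    @pytest.mark.parametrize(
        "age,sex,expected",
        [(70, "M", 163.996), (65, "F", 153.4515), (0, "M", 166.7)],
    )
    def test_polynomial_evaluation(self, age, sex, expected):
        assert g.height_mean(age, sex) == pytest.approx(expected, abs=1e-3)

    def test_strictly_decreasing_over_domain(self):
        ages = np.linspace(65, 95, 200)
        for sex in ("M", "F"):
            h = np.array([g.height_mean(a, sex) for a in ages])
            assert np.all(np.diff(h) < 0)

    def test_unknown_sex_rejected(self):
        with pytest.raises(ValueError):
            g.height_mean(70, "X")

    def test_zero_residual_equals_mean(self, default_spec, rng):
        spec = default_spec.model_copy(update={"height_resid_sd_male": 0.0})
        assert g.sample_height(70, "M", spec, rng) == g.height_mean(70, "M", spec)

    def test_residual_moments(self, default_spec):
        rng = np.random.default_rng(1)
        draws = np.array(
            [g.sample_height(70, "M", default_spec, rng) for _ in range(20_000)]
        )
        assert draws.mean() == pytest.approx(164.0, abs=0.1)
        assert draws.std(ddof=1) == pytest.approx(6.3, abs=0.1)


class TestWeight:
    @pytest.mark.parametrize(
        "age,sex,expected",
        [(69.6, "M", 65.35), (79.5, "F", 53.68), (69.6, "F", 57.95)],
    )
    def test_band_mean_calibration(self, age, sex, expected):
        assert g.weight_mean(age, sex) == pytest.approx(expected, abs=0.2)

    def test_flat_curve_when_rate_zero(self, default_spec):
        spec = default_spec.model_copy(update={"weight_exp_male": (70.0, 0.0)})
        assert g.weight_mean(65, "M", spec) == g.weight_mean(95, "M", spec) == 70.0

    def test_nonpositive_scale_rejected(self, default_spec):
        spec = default_spec.model_copy(update={"weight_exp_male": (-1.0, 0.0)})
        with pytest.raises(ValueError):
            g.weight_mean(70, "M", spec)


class TestBSAAndCardiacOutput:
    @pytest.mark.parametrize(
        "wt,ht,expected", [(61.32, 157.45, 1.600), (58.14, 156.29, 1.557)]
    )
    def test_power_law(self, wt, ht, expected):
        assert g.bsa(wt, ht) == pytest.approx(expected, abs=1e-3)

    def test_power_law_homogeneity(self):
        base = g.bsa(60.0, 160.0)
        assert g.bsa(120.0, 160.0) == pytest.approx(base * 2**0.4259, rel=1e-12)

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            g.bsa(0.0, 160.0)

    @pytest.mark.parametrize(
        "bsa_m2,age,expected",
        [(1.600, 70, 273.328), (1.664, 70, 284.261), (1.0, 0, 205.9)],
    )
    def test_cardiac_output_values(self, bsa_m2, age, expected):
        assert g.cardiac_output(bsa_m2, age) == pytest.approx(expected, abs=0.05)

    def test_cardiac_output_linear_in_bsa(self):
        assert g.cardiac_output(2.4, 72) == pytest.approx(
            2 * g.cardiac_output(1.2, 72), rel=1e-12
        )

    def test_out_of_domain_age_rejected(self):
        with pytest.raises(ValueError):
            g.cardiac_output(1.6, 420)


class TestSerumCreatinine:
    @pytest.mark.parametrize(
        "sex,age,mean,sd",
        [
            ("M", 70, 83.14, 15.89),
            ("F", 70, 67.68, 30.16),
            ("M", 80, 93.48, 39.6),
            ("F", 80, 72.02, 25.99),
        ],
    )
    def test_band_moment_matching(self, default_spec, sex, age, mean, sd):
        rng = np.random.default_rng(5)
        draws = np.array(
            [g.sample_serum_creatinine(sex, age, default_spec, rng)
             for _ in range(100_000)]
        )
        assert draws.mean() == pytest.approx(mean, rel=0.01)
        assert draws.std(ddof=1) == pytest.approx(sd, rel=0.01)

    def test_zero_sd_returns_band_mean(self, default_spec, rng):
        spec = default_spec.model_copy(deep=True)
        spec.scr_dist["M|65-75"].sd = 0.0
        assert g.sample_serum_creatinine("M", 70, spec, rng) == 83.14

    def test_pre_geriatric_age_rejected(self, default_spec, rng):
        with pytest.raises(ValueError):
            g.sample_serum_creatinine("M", 50, default_spec, rng)


class TestRenalFunction:
    def test_cockcroft_gault_hand_oracle(self):
        # ((140-70)*65) / (72 * 83.14/88.4) = 67.19 mL/min, 4 significant figures
        assert g.creatinine_clearance_cg(70, 65, 83.14, "M") == pytest.approx(
            67.19, abs=0.005
        )

    def test_female_factor(self):
        male = g.creatinine_clearance_cg(70, 65, 83.14, "M")
        assert g.creatinine_clearance_cg(70, 65, 83.14, "F") == pytest.approx(
            0.85 * male, rel=1e-12
        )

    def test_unit_conversion_identity(self):
        # scr = 88.4 µmol/L is exactly 1 mg/dL
        assert g.creatinine_clearance_cg(70, 72, 88.4, "M") == pytest.approx(70.0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            g.creatinine_clearance_cg(140, 65, 83.14, "M")
        with pytest.raises(ValueError):
            g.creatinine_clearance_cg(70, 65, 0.0, "M")

    @pytest.mark.parametrize(
        "clcr,bsa,expected", [(67.19, 1.73, 67.19), (5.0, 1.73, 15.0), (500.0, 1.73, 400.0)]
    )
    def test_gfr_cap(self, clcr, bsa, expected):
        assert g.apply_gfr_cap(clcr, bsa) == pytest.approx(expected)

    def test_cap_denormalises_by_bsa(self):
        # same normalised value, different body size
        assert g.apply_gfr_cap(5.0, 2.0) == pytest.approx(15.0 * 2.0 / 1.73)


class TestOrganWeights:
    def test_population_means_match_validation_table(self, pop_frame):
        band = pop_frame[pop_frame.age_yr <= 75]
        assert band[band.sex == "M"].liver_weight_g.mean() == pytest.approx(
            1173.4, abs=15
        )
        assert band[band.sex == "F"].kidney_weight_g.mean() == pytest.approx(
            243.4, abs=5
        )

    def test_zero_slope_is_invalid_spec(self):
        with pytest.raises(ValidationError):
            g.PopulationSpec(organ_slope_liver_male=0.0)

    def test_unknown_organ_rejected(self):
        with pytest.raises(ValueError):
            g.organ_weight(1.6, "M", "pancreas")


class TestSubjectAssembly:
    def test_invariants_hold_for_every_subject(self, population_1k, default_spec):
        for s in population_1k:
            assert default_spec.age_min <= s.age <= default_spec.age_max
            # flow fractions over perfused compartments sum to 1
            flow_sum = sum(v for t, v in s.tissue_flows.items() if t != "lung")
            assert flow_sum / s.cardiac_output == pytest.approx(1.0, abs=1e-9)
            # tissue volumes close the body-volume balance
            total_vol = sum(s.tissue_volumes.values())
            assert total_vol <= s.weight / 1.05 * 1.02
            # GFR respects the de-normalised cap
            norm = s.gfr * 1.73 / s.bsa
            assert 15.0 - 1e-9 <= norm <= 400.0 + 1e-9
            assert s.hepatic_blood_flow == pytest.approx(0.245 * s.cardiac_output)
            for v in (s.height, s.weight, s.bsa, s.cardiac_output,
                      s.serum_creatinine, s.gfr, s.liver_weight, s.kidney_weight):
                assert v > 0

    def test_seeded_determinism(self, default_spec):
        a = g.population_frame(g.generate_population(default_spec, 50, seed=9))
        b = g.population_frame(g.generate_population(default_spec, 50, seed=9))
        pd.testing.assert_frame_equal(a, b, check_exact=True)

    def test_subject_streams_stable_in_n(self, default_spec):
        few = g.generate_population(default_spec, 5, seed=4)
        many = g.generate_population(default_spec, 20, seed=4)
        for s1, s2 in zip(few, many):
            assert s1.age == s2.age and s1.height == s2.height

    def test_height_percentiles_match_direct_monte_carlo(self, default_spec):
        """Independent re-simulation oracle: same equations, vectorised
        numpy implementation written from scratch."""
        rng = np.random.default_rng(123)
        n = 4000
        d = default_spec.age_dist
        cdf_hi = 1 - np.exp(-(30.0 / d.scale) ** d.shape)
        u = rng.uniform(0, cdf_hi, n)
        ages = 65.0 + d.scale * (-np.log1p(-u)) ** (1 / d.shape)
        male = rng.uniform(size=n) < 0.5
        h = np.where(
            male,
            166.7 + 0.1356 * ages - 0.002489 * ages**2,
            154.6 + 0.1889 * ages - 0.003178 * ages**2,
        ) + np.where(male, 6.3, 5.9) * rng.standard_normal(n)

        sim = g.population_frame(g.generate_population(default_spec, n, seed=12))
        for q in (5, 95):
            assert np.percentile(sim.height_cm, q) == pytest.approx(
                np.percentile(h, q), abs=1.0
            )

    def test_sex_codes_normalised(self):
        assert normalize_sex("male") == "M" and normalize_sex("f") == "F"
        with pytest.raises(ValueError):
            normalize_sex("?")


class TestSpecValidation:
    @pytest.mark.parametrize(
        "update",
        [
            {"male_fraction": 1.5},
            {"age_min": 60.0},
            {"height_resid_sd_male": -1.0},
            {"organ_slope_kidney_female": -5.0},
        ],
    )
    def test_invalid_specs_rejected(self, update):
        with pytest.raises(ValidationError):
            g.PopulationSpec(**update)

    def test_yaml_round_trip(self, default_spec, tmp_path):
        path = tmp_path / "spec.yaml"
        default_spec.to_yaml(path)
        assert g.PopulationSpec.from_yaml(path) == default_spec
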