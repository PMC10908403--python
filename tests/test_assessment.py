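import numpy as np
import pandas as pd
import pytest

from vascage.assessment import (AssessmentConfig, bland_altman, correlate,
                                noise_robustness, run_full_assessment,
                                sensitivity_index)
from vascage.synthetic import SyntheticSpec, make_population


class TestCorrelate:
    def test_perfect_linear_relation(self):
        x = np.linspace(0, 10, 20)
        res = correlate(2 * x + 1, x)
        assert res.r_p == pytest.approx(1.0)
        assert res.r_s == pytest.approx(1.0)

    def test_monotone_nonlinearity_separates_coefficients(self):
        x = np.linspace(0, 5, 30)
        res = correlate(np.exp(x), x)
        assert res.r_s == pytest.approx(1.0)
        assert res.r_p < 1.0

    def test_null_pairing_is_near_zero(self, rng):
        x = rng.normal(size=1000)
        y = rng.normal(size=1000)
        assert abs(correlate(x, y).r_s) < 0.08

    def test_spearman_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=50)
        y = x ** 3 + rng.normal(scale=0.1, size=50)
        base = correlate(y, x).r_s
        assert correlate(np.exp(y), x).r_s == pytest.approx(base)
        assert correlate(y, np.expm1(x)).r_s == pytest.approx(base)

    def test_missing_pairs_dropped(self):
        x = [1.0, None, 3.0, 4.0, np.nan, 6.0]
        y = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        res = correlate(x, y)
        assert res.n == 4
        assert res.r_p == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            correlate([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBlandAltman:
    def test_identical_measurements(self):
        res = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.bias == 0.0 and res.loa_half_width == 0.0

    def test_constant_offset(self):
        x = np.array([4.0, 5.0, 6.0])
        res = bland_altman(x + 1.7, x)
        assert res.bias == pytest.approx(1.7)
        assert res.loa_half_width == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_triple(self):
        # differences {0.1, 0.3, 0.5}: population SD 0.16330
        res = bland_altman([0.1, 0.3, 0.5], [0.0, 0.0, 0.0])
        assert res.bias == pytest.approx(0.3)
        assert res.loa_half_width == pytest.approx(0.3201, abs=5e-4)

    def test_sample_sd_flag(self):
        res = bland_altman([0.1, 0.3, 0.5], [0.0, 0.0, 0.0], ddof=1)
        assert res.loa_half_width == pytest.approx(1.96 * 0.2, abs=1e-9)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [1.0])


class TestSensitivityIndex:
    def _keys(self, ages=(25, 45, 65)):
        for age in ages:
            for direction in (+1, -1):
                yield age, direction

    def test_no_response_gives_zero(self):
        baselines = {a: 10.0 for a in (25, 45, 65)}
        values = {(a, "heart rate", d): 10.0 for a, d in self._keys()}
        (res,) = sensitivity_index(values, baselines)
        assert res.i_percent == 0.0
        assert res.category == "cardiac"

    def test_antisymmetric_response_is_its_magnitude(self):
        baselines = {a: 10.0 for a in (25, 45, 65)}
        values = {(a, "input PWV", d): 10.0 * (1 + d * 0.05)
                  for a, d in self._keys()}
        (res,) = sensitivity_index(values, baselines)
        assert res.i_percent == pytest.approx(5.0)

    def test_symmetric_response_cancels(self):
        # +5% in both directions: the signed average is zero
        baselines = {a: 10.0 for a in (25, 45, 65)}
        values = {(a, "stroke volume", d): 10.5 for a, d in self._keys()}
        (res,) = sensitivity_index(values, baselines)
        assert res.i_percent == pytest.approx(0.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="zero baseline"):
            sensitivity_index({(25, "heart rate", 1): 1.0}, {25: 0.0})

    def test_bad_direction_rejected(self):
        with pytest.raises(ValueError, match="direction"):
            sensitivity_index({(25, "heart rate", 2): 1.0}, {25: 1.0})


@pytest.fixture(scope="module")
def tiny_population():
    return make_population(SyntheticSpec(n_subjects=12, seed=6))


@pytest.fixture(scope="module")
def assessment_outputs(tmp_path_factory):
    config = AssessmentConfig(
        spec=SyntheticSpec(n_subjects=16, seed=12),
        snr_levels=(np.inf, 20.0),
        out_dir=tmp_path_factory.mktemp("assess"))
    return config, run_full_assessment(config)


class TestNoiseRobustness:
    def test_infinite_snr_reproduces_clean_correlations(self,
                                                        tiny_population):
        table = noise_robustness(tiny_population, [np.inf], seed=0)
        clean = noise_robustness(tiny_population, [np.inf], seed=99)
        merged = table.merge(clean, on=["snr_db", "index"])
        assert np.allclose(merged["r_s_x"], merged["r_s_y"])

    def test_fixed_seed_reproducible(self, tiny_population):
        a = noise_robustness(tiny_population, [20.0], seed=3)
        b = noise_robustness(tiny_population, [20.0], seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_noise_reduces_transit_index_correlation(self, tiny_population):
        table = noise_robustness(tiny_population, [np.inf, 15.0], seed=1)
        piv = table.pivot(index="index", columns="snr_db", values="r_s")
        assert abs(piv.loc["cfPWV", 15.0]) <= abs(piv.loc["cfPWV", np.inf])


class TestRunFullAssessment:
    def test_writes_all_tables(self, assessment_outputs):
        config, _ = assessment_outputs
        for name in ("panels.csv", "correlations.csv", "bland_altman.csv",
                     "sensitivity.csv", "noise_robustness.csv"):
            assert (config.out_dir / name).exists()

    def test_correlations_sorted_descending_within_cohort(
            self, assessment_outputs):
        _, results = assessment_outputs
        corr = results["correlations"]
        for _, grp in corr.groupby("cohort"):
            assert grp["r_s"].is_monotonic_decreasing

    def test_bland_altman_covers_pwv_indices(self, assessment_outputs):
        _, results = assessment_outputs
        assert set(results["bland_altman"]["index"]) == {
            "aoPWV", "cfPWV", "baPWV", "cbPWV", "crPWV", "ftPWV"}

    def test_rerun_is_byte_identical(self, assessment_outputs, tmp_path):
        import dataclasses
        config, _ = assessment_outputs
        rerun = dataclasses.replace(config, out_dir=tmp_path / "again")
        run_full_assessment(rerun)
        for name in ("panels.csv", "correlations.csv", "noise_robustness.csv"):
            assert (config.out_dir / name).read_bytes() \
                == (rerun.out_dir / name).read_bytes()
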