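"""RMSE/RPD metrics, evaluation reports, grid ranking, diagnostics."""

import numpy as np
import pytest

from oleanir import GeneratorConfig
from oleanir.evaluate import (
    DEFAULT_GRID_CODES,
    EvaluationReport,
    evaluate_model,
    grid_search,
    interpret_rpd,
    observed_predicted_fit,
    rmse,
    rpd,
)
from oleanir.simulate import (
    generate_profiles,
    generate_reference_values,
    generate_spectra,
)


class TestRmse:
    def test_perfect_prediction_is_zero(self):
        assert rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_two_term_case(self):
        assert rmse([0.0, 2.0], [0.0, 0.0]) == pytest.approx(np.sqrt(2.0))

    def test_invariant_to_pair_permutation(self):
        f = np.array([1.0, 4.0, 2.0, 8.0])
        y = np.array([0.5, 4.5, 1.0, 9.0])
        perm = [2, 0, 3, 1]
        assert rmse(f, y) == pytest.approx(rmse(f[perm], y[perm]))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rmse([], [])


class TestRpd:
    def test_ratio(self):
        assert rpd(0.5, 0.25) == pytest.approx(2.0)

    def test_equal_sd_and_rmse_give_one(self):
        assert rpd(0.3, 0.3) == pytest.approx(1.0)

    def test_linearity_in_sd(self):
        assert rpd(1.0, 0.4) == pytest.approx(2 * rpd(0.5, 0.4))

    def test_zero_rmse_warns_and_returns_infinity(self):
        with pytest.warns(RuntimeWarning):
            assert rpd(0.5, 0.0) == np.inf

    def test_monotone_decreasing_in_error_magnitude(self):
        y = np.array([0.5, 0.7, 0.9, 0.6, 0.8])
        resid = np.array([0.01, -0.02, 0.015, -0.01, 0.02])
        sd = y.std(ddof=1)
        values = [rpd(sd, rmse(y + s * resid, y)) for s in (1.0, 2.0, 4.0)]
        assert values[0] > values[1] > values[2]


class TestInterpretRpd:
    @pytest.mark.parametrize("value,category", [
        (3.01, "quality control"),
        (3.0, "quality control"),
        (2.69, "screening"),
        (2.0, "screening"),
        (1.99, "not recommended"),
        (1.5, "not recommended"),
    ])
    def test_banding(self, value, category):
        assert interpret_rpd(value) == category

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            interpret_rpd(0.0)


class TestObservedPredictedFit:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        fit = observed_predicted_fit(y, y)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_doubling_prediction_doubles_slope(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        fit = observed_predicted_fit(y, 2.0 * y)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_matches_generic_least_squares_oracle(self):
        from scipy import stats
        rng = np.random.default_rng(1)
        y = rng.normal(size=25)
        f = 0.8 * y + 0.1 + 0.2 * rng.normal(size=25)
        fit = observed_predicted_fit(y, f)
        oracle = stats.linregress(y, f)
        assert fit.slope == pytest.approx(oracle.slope)
        assert fit.intercept == pytest.approx(oracle.intercept)
        assert fit.r_squared == pytest.approx(oracle.rvalue ** 2)

    def test_constant_observed_rejected(self):
        with pytest.raises(ValueError):
            observed_predicted_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


@pytest.fixture(scope="module")
def noise_free_case():
    """Small dataset with no reference noise and an exactly linear y."""
    cfg = GeneratorConfig(
        n_samples=40, seed=21, noise_sd_reference=0.0,
        multiplicative_scatter_sd=0.02, additive_scatter_sd=0.005,
        spectral_noise_sd=0.0,
    )
    profiles = generate_profiles(cfg)
    spectra = generate_spectra(profiles, cfg)
    ref = generate_reference_values(profiles, "DPPH", cfg, noise_sd=0.0,
                                    clip_range=None)
    return spectra, ref


class TestEvaluateModel:
    def test_exactly_linear_chain_predicts_to_machine_precision(self):
        # With every stochastic spectral distortion off and no scatter
        # normalisation, spectra are exactly linear in concentrations
        # (the SG derivative removes the class of baselines it sees), so
        # PLS must recover the affine response almost exactly.
        from oleanir.preprocess import PretreatmentSpec

        cfg = GeneratorConfig(
            n_samples=30, seed=22, noise_sd_reference=0.0,
            multiplicative_scatter_sd=0.0, additive_scatter_sd=0.0,
            spectral_noise_sd=0.0,
        )
        profiles = generate_profiles(cfg)
        spectra = generate_spectra(profiles, cfg)
        ref = generate_reference_values(profiles, "DPPH", cfg, noise_sd=0.0,
                                        clip_range=None)
        spec = PretreatmentSpec(scatter="NONE", deriv_order=2,
                                deriv_window=19, smooth_window=5)
        report = evaluate_model(spectra, ref, spec, max_lv=10)
        assert report.prediction.r_squared >= 0.9999

    def test_noise_free_data_predicts_well_after_scatter_correction(
            self, noise_free_case):
        # SNV/SNV-style row normalisation is mildly nonlinear in the
        # concentrations, which caps R2 just below 1 even without noise.
        spectra, ref = noise_free_case
        report = evaluate_model(spectra, ref, "SNV-2.19.5", max_lv=12)
        assert report.prediction.r_squared >= 0.97

    def test_default_mode_never_trains_on_prediction_set(self, noise_free_case):
        spectra, ref = noise_free_case
        report = evaluate_model(spectra, ref, "SNV-2.19.5", max_lv=8)
        pred_ids = set(spectra.sample_ids) - set(report.training_ids)
        assert len(report.training_ids) == report.cv.n
        assert len(pred_ids) == report.prediction.n

    def test_paper_mode_changes_only_prediction_entries(self, noise_free_case):
        spectra, ref = noise_free_case
        default = evaluate_model(spectra, ref, "SNV-2.19.5", max_lv=8)
        leaky = evaluate_model(spectra, ref, "SNV-2.19.5", max_lv=8,
                               paper_mode=True)
        assert leaky.calibration == default.calibration
        assert leaky.cv == default.cv
        assert leaky.selected_lv == default.selected_lv
        # the leaky protocol has seen Set 2, so it cannot do worse there
        assert leaky.prediction.rmse <= default.prediction.rmse + 1e-12

    def test_report_round_trips_through_json(self, noise_free_case, tmp_path):
        spectra, ref = noise_free_case
        report = evaluate_model(spectra, ref, "SNV-2.19.5", max_lv=6)
        path = tmp_path / "report.json"
        report.to_json(path)
        assert EvaluationReport.from_json(path) == report


class TestGridSearch:
    def test_default_grid_is_the_six_study_codes(self):
        assert set(DEFAULT_GRID_CODES) == {
            "MSC-1.19.5", "SNV-2.13.9", "MSC-2.19.5",
            "SNV-2.19.5", "SNV-2.5.19", "MSC-2.5.19",
        }

    def test_single_code_gives_single_report(self, noise_free_case):
        spectra, ref = noise_free_case
        reports = grid_search(spectra, ref, ["SNV-2.5.5"], max_lv=6)
        assert len(reports) == 1

    def test_ranking_follows_rpd_then_r2_then_rmsep(self, noise_free_case):
        spectra, ref = noise_free_case
        reports = grid_search(spectra, ref, ["MSC-1.19.5", "SNV-2.19.5",
                                             "SNV-2.13.9"], max_lv=8)
        keys = [(-r.prediction.rpd, -r.prediction.r_squared, r.prediction.rmse)
                for r in reports]
        assert keys == sorted(keys)

    def test_empty_code_list_rejected(self, noise_free_case):
        spectra, ref = noise_free_case
        with pytest.raises(ValueError):
            grid_search(spectra, ref, [])

    def test_all_codes_failing_raises_aggregate_error(self, noise_free_case):
        spectra, ref = noise_free_case
        with pytest.raises((RuntimeError, ValueError)):
            grid_search(spectra, ref, ["BAD-1.1"])
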