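"""Pretreatments: SG smoothing/derivatives, SNV, MSC, code parsing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oleanir.preprocess import (
    IDENTITY,
    PretreatmentSpec,
    apply_pretreatment,
    msc,
    parse_pretreatment_code,
    savitzky_golay,
    snv,
)
from oleanir.spectra import SpectraSet


def spectra_from(values, wavenumbers=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if wavenumbers is None:
        wavenumbers = np.arange(values.shape[1], dtype=float)[::-1]
    return SpectraSet(wavenumbers=np.asarray(wavenumbers, dtype=float),
                      absorbance=values)


class TestSavitzkyGolay:
    def test_smoothing_preserves_linear_ramp(self):
        nu = np.arange(100.0, 0.0, -1.0)
        ramp = 3.0 - 0.02 * nu
        out = savitzky_golay(spectra_from(ramp[None, :], nu), window=5,
                             polyorder=2, deriv_order=0)
        np.testing.assert_allclose(out.absorbance[0], ramp, atol=1e-10)

    def test_first_derivative_of_square_is_linear(self):
        nu = np.arange(50.0, 0.0, -1.0)
        out = savitzky_golay(spectra_from((nu ** 2)[None, :], nu), window=5,
                             polyorder=2, deriv_order=1)
        interior = slice(2, -2)
        np.testing.assert_allclose(out.absorbance[0][interior],
                                   2.0 * nu[interior], atol=1e-8)

    def test_second_derivative_of_square_is_constant(self):
        nu = np.arange(50.0, 0.0, -1.0)
        out = savitzky_golay(spectra_from((nu ** 2)[None, :], nu), window=5,
                             polyorder=2, deriv_order=2)
        interior = slice(2, -2)
        np.testing.assert_allclose(out.absorbance[0][interior], 2.0, atol=1e-8)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            savitzky_golay(spectra_from(np.ones((1, 10))), window=4)

    def test_non_uniform_grid_rejected(self):
        nu = np.array([100.0, 96.0, 91.0, 87.0, 83.0, 79.0, 75.0])
        with pytest.raises(ValueError, match="uniform"):
            savitzky_golay(spectra_from(np.ones((1, 7)), nu), window=5)

    @given(st.tuples(st.floats(-2, 2), st.floats(-2, 2), st.floats(-2, 2)))
    @settings(deadline=None, derandomize=True)
    def test_smoothing_reproduces_any_quadratic_in_the_interior(self, coeffs):
        a, b, c = coeffs
        nu = np.arange(30.0, 0.0, -1.0)
        poly = a + b * nu + c * nu ** 2
        out = savitzky_golay(spectra_from(poly[None, :], nu), window=7,
                             polyorder=2, deriv_order=0)
        interior = slice(3, -3)
        np.testing.assert_allclose(out.absorbance[0][interior], poly[interior],
                                   atol=1e-7)


class TestSnv:
    def test_simple_row(self):
        out = snv(spectra_from([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out.absorbance[0], [-1.0, 0.0, 1.0])

    def test_rows_have_zero_mean_unit_sd(self, toy_spectra):
        out = snv(toy_spectra)
        np.testing.assert_allclose(out.absorbance.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.absorbance.std(axis=1, ddof=1), 1.0,
                                   atol=1e-12)

    def test_idempotence(self, toy_spectra):
        once = snv(toy_spectra)
        twice = snv(once)
        np.testing.assert_allclose(twice.absorbance, once.absorbance, atol=1e-12)

    def test_invariance_to_row_affine_transforms(self, toy_spectra):
        scaled = toy_spectra.copy_with(2.5 * toy_spectra.absorbance + 3.0)
        np.testing.assert_allclose(snv(scaled).absorbance,
                                   snv(toy_spectra).absorbance, atol=1e-10)

    def test_constant_row_error_names_sample(self):
        s = SpectraSet(wavenumbers=np.array([3.0, 2.0, 1.0]),
                       absorbance=np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]]),
                       sample_ids=["ok", "flat"])
        with pytest.raises(ValueError, match="flat"):
            snv(s)


class TestMsc:
    def test_affine_family_maps_to_reference(self, toy_spectra):
        ref = toy_spectra.absorbance.mean(axis=0)
        fam = toy_spectra.copy_with(
            1.0 + 2.0 * np.tile(ref, (toy_spectra.n_samples, 1)))
        out = msc(fam, reference=ref)
        np.testing.assert_allclose(out.absorbance,
                                   np.tile(ref, (toy_spectra.n_samples, 1)),
                                   atol=1e-10)

    def test_reference_is_fixed_point(self, toy_spectra):
        ref = toy_spectra.absorbance.mean(axis=0)
        row = toy_spectra.subset([0]).copy_with(ref[None, :])
        np.testing.assert_allclose(msc(row, reference=ref).absorbance[0], ref,
                                   atol=1e-12)

    def test_corrected_rows_regress_to_unit_line(self, toy_spectra):
        # refit oracle: regressing each corrected row on the reference
        # must give intercept 0 and slope 1
        out = msc(toy_spectra)
        ref = toy_spectra.absorbance.mean(axis=0)
        for row in out.absorbance:
            slope, intercept = np.polyfit(ref, row, 1)
            assert abs(slope - 1.0) <= 1e-10
            assert abs(intercept) <= 1e-10

    def test_near_zero_slope_error_names_sample(self):
        s = SpectraSet(wavenumbers=np.array([3.0, 2.0, 1.0]),
                       absorbance=np.array([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]]),
                       sample_ids=["ok", "flat"])
        with pytest.raises(ValueError, match="flat"):
            msc(s, reference=np.array([1.0, 2.0, 3.0]))


class TestCodeParser:
    def test_msc_code(self):
        spec = parse_pretreatment_code("MSC-1.19.5")
        assert (spec.scatter, spec.deriv_order, spec.deriv_window,
                spec.smooth_window) == ("MSC", 1, 19, 5)

    def test_snv_code_with_wide_smoothing(self):
        spec = parse_pretreatment_code("SNV-2.5.19")
        assert (spec.scatter, spec.deriv_order, spec.deriv_window,
                spec.smooth_window) == ("SNV", 2, 5, 19)

    def test_round_trip(self):
        for code in ("MSC-1.19.5", "SNV-2.13.9", "SNV-2.19.5"):
            assert parse_pretreatment_code(code).code == code

    @pytest.mark.parametrize("bad", ["ABC-9.9", "MSC-3.5.5", "SNV-1.4.5",
                                     "SNV-1.5.4", "MSC-1.5", "msc-1.5.5"])
    def test_malformed_codes_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_pretreatment_code(bad)


class TestApplyPretreatment:
    def test_identity_spec_is_identity(self, toy_spectra):
        out = apply_pretreatment(toy_spectra, IDENTITY)
        np.testing.assert_array_equal(out.absorbance, toy_spectra.absorbance)

    def test_snv_last_normalizes_rows(self):
        rng = np.random.default_rng(0)
        nu = np.arange(5000.0, 4000.0, -4.0)
        s = SpectraSet(wavenumbers=nu,
                       absorbance=rng.uniform(0.1, 1.0, (6, nu.size)))
        out = apply_pretreatment(s, "SNV-2.19.5")
        np.testing.assert_allclose(out.absorbance.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.absorbance.std(axis=1, ddof=1), 1.0,
                                   atol=1e-10)

    def test_pipeline_equals_manual_composition(self):
        rng = np.random.default_rng(1)
        nu = np.arange(5000.0, 4000.0, -4.0)
        s = SpectraSet(wavenumbers=nu,
                       absorbance=rng.uniform(0.1, 1.0, (6, nu.size)))
        out = apply_pretreatment(s, "MSC-2.19.5")
        manual = msc(savitzky_golay(savitzky_golay(s, 19, 2, 2), 5, 2, 0))
        np.testing.assert_allclose(out.absorbance, manual.absorbance, atol=1e-12)

    def test_scatter_first_option_changes_order(self):
        rng = np.random.default_rng(2)
        nu = np.arange(5000.0, 4600.0, -4.0)
        s = SpectraSet(wavenumbers=nu,
                       absorbance=rng.uniform(0.1, 1.0, (5, nu.size)))
        spec = parse_pretreatment_code("SNV-1.5.5")
        swapped = apply_pretreatment(s, spec, scatter_first=True)
        manual = savitzky_golay(savitzky_golay(snv(s), 5, 2, 1), 5, 2, 0)
        np.testing.assert_allclose(swapped.absorbance, manual.absorbance,
                                   atol=1e-12)

    def test_sample_ids_and_axis_preserved(self, toy_spectra):
        out = apply_pretreatment(toy_spectra, "SNV-2.5.5")
        assert out.sample_ids == toy_spectra.sample_ids
        np.testing.assert_array_equal(out.wavenumbers, toy_spectra.wavenumbers)

    def test_stage_errors_carry_stage_name(self):
        s = SpectraSet(wavenumbers=np.array([3.0, 2.0, 1.0]),
                       absorbance=np.array([[1.0, 1.0, 1.0]]))
        with pytest.raises(ValueError, match="scatter"):
            apply_pretreatment(s, PretreatmentSpec(scatter="SNV"))
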