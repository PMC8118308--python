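"""ROI extraction, spline smoothing, NNLS unmixing, band flags and
composition rules."""

import numpy as np
import pytest

from crystalscope.io import Roi, RoiShape, Spectrum, WavenumberAxis
from crystalscope.spectra import (
    BandWindow,
    CompositionConfig,
    DominantClass,
    ReferenceLibrary,
    classify_composition,
    decompose_spectrum,
    detect_band,
    extract_roi_spectrum,
    smooth_spectrum,
)
from crystalscope.synth import (
    SceneClass,
    Species,
    SpectralScene,
    generate_cube,
    synth_reference_spectrum,
)


class TestExtractRoiSpectrum:
    def test_single_pixel_roi_is_that_pixel(self, ch_axis):
        cmap = np.full((8, 8), SceneClass.PROTEIN.value, dtype=object)
        cube, _ = generate_cube(SpectralScene(class_map=cmap, noise_sd=0.02, seed=0), ch_axis)
        roi = Roi(shape=RoiShape.MASK, mask=np.eye(8, dtype=bool) * 0)
        roi.mask[2, 3] = True
        spec = extract_roi_spectrum(cube, roi)
        np.testing.assert_array_equal(spec.intensities, cube.data[2, 3])

    def test_two_pixel_roi_is_arithmetic_mean(self, ch_axis):
        cmap = np.full((8, 8), SceneClass.PROTEIN.value, dtype=object)
        cube, _ = generate_cube(SpectralScene(class_map=cmap, noise_sd=0.05, seed=1), ch_axis)
        mask = np.zeros((8, 8), dtype=bool)
        mask[1, 1] = mask[5, 6] = True
        spec = extract_roi_spectrum(cube, Roi(shape=RoiShape.MASK, mask=mask))
        np.testing.assert_allclose(
            spec.intensities, (cube.data[1, 1] + cube.data[5, 6]) / 2, atol=1e-12
        )

    def test_constant_class_region_recovers_reference(self, ch_axis):
        cmap = np.full((8, 8), SceneClass.FC_CRYSTAL.value, dtype=object)
        cube, _ = generate_cube(SpectralScene(class_map=cmap, noise_sd=0.0, seed=0), ch_axis)
        roi = Roi(shape=RoiShape.DISK, center=(4.0, 4.0), radius=2.5)
        spec = extract_roi_spectrum(cube, roi)
        ref = synth_reference_spectrum(Species.CHOLESTEROL_MONOHYDRATE, ch_axis)
        np.testing.assert_allclose(spec.intensities, ref.intensities, atol=1e-12)


class TestSmoothSpectrum:
    def test_exact_at_original_knots(self, ch_axis, rng):
        spec = Spectrum(ch_axis.values(), rng.random(ch_axis.n_channels))
        fine = smooth_spectrum(spec, 1.0)
        idx = np.searchsorted(fine.wavenumbers_cm1, spec.wavenumbers_cm1)
        np.testing.assert_allclose(
            fine.intensities[idx], spec.intensities, atol=1e-9
        )

    def test_reproduces_linear_ramp_everywhere(self, ch_axis):
        w = ch_axis.values()
        spec = Spectrum(w, 0.01 * w - 20.0)
        fine = smooth_spectrum(spec, 1.0)
        np.testing.assert_allclose(
            fine.intensities, 0.01 * fine.wavenumbers_cm1 - 20.0, atol=1e-9
        )

    def test_reproduces_cubic_polynomial(self, ch_axis):
        w = ch_axis.values()
        x = (w - 2950.0) / 100.0
        spec = Spectrum(w, x**3 - 2 * x**2 + x)
        fine = smooth_spectrum(spec, 1.0)
        xf = (fine.wavenumbers_cm1 - 2950.0) / 100.0
        np.testing.assert_allclose(fine.intensities, xf**3 - 2 * xf**2 + xf, atol=1e-9)

    def test_gaussian_band_argmax_within_2_cm1_of_true_center(self, ch_axis):
        # oracle: densely sampled analytic Gaussian
        center, sigma = 2953.0, 12.0
        w = ch_axis.values()
        spec = Spectrum(w, np.exp(-0.5 * ((w - center) / sigma) ** 2))
        fine = smooth_spectrum(spec, 1.0)
        est = fine.wavenumbers_cm1[np.argmax(fine.intensities)]
        assert abs(est - center) <= 2.0

    def test_coarser_resample_step_rejected(self, ch_axis):
        spec = Spectrum(ch_axis.values(), np.ones(ch_axis.n_channels))
        with pytest.raises(ValueError, match="finer"):
            smooth_spectrum(spec, 5.0)


class TestDecomposeSpectrum:
    def test_noiseless_mixture_recovered_exactly(self, ch_library):
        A = ch_library.matrix()
        y = 0.7 * A[:, 2] + 0.3 * A[:, 3]  # linoleate + protein
        coef, rms = decompose_spectrum(Spectrum(ch_library.wavenumbers_cm1, y), ch_library)
        total = sum(coef.values())
        assert coef[Species.CHOLESTERYL_LINOLEATE] / total == pytest.approx(0.7, abs=1e-6)
        assert coef[Species.PROTEIN] / total == pytest.approx(0.3, abs=1e-6)
        # the min-baseline shift leaves a tiny representation residual
        assert rms < 1e-6

    def test_pure_basis_member_dominates(self, ch_library):
        y = ch_library.entries[Species.CHOLESTEROL_MONOHYDRATE].intensities
        coef, _ = decompose_spectrum(Spectrum(ch_library.wavenumbers_cm1, y), ch_library)
        total = sum(coef.values())
        assert coef[Species.CHOLESTEROL_MONOHYDRATE] / total > 0.99

    def test_matches_simplex_grid_search_on_two_member_library(self, ch_axis, rng):
        # brute-force oracle: scan mixing weight at 0.01 steps
        lib2 = ReferenceLibrary.from_band_model(
            ch_axis, species=(Species.CHOLESTERYL_LINOLEATE, Species.PROTEIN)
        )
        A = lib2.matrix()
        for true_w in (0.15, 0.5, 0.83):
            y = true_w * A[:, 0] + (1 - true_w) * A[:, 1]
            yn = (y - y.min()) / (y - y.min()).max()
            grid = np.arange(0, 1.0001, 0.01)
            errs = [
                np.linalg.norm(yn - (g * A[:, 0] + (1 - g) * A[:, 1]) * s)
                for g in grid
                for s in (np.dot(yn, g * A[:, 0] + (1 - g) * A[:, 1])
                          / np.dot(g * A[:, 0] + (1 - g) * A[:, 1],
                                   g * A[:, 0] + (1 - g) * A[:, 1]),)
            ]
            best = grid[int(np.argmin(errs))]
            coef, _ = decompose_spectrum(Spectrum(lib2.wavenumbers_cm1, y), lib2)
            frac = coef[Species.CHOLESTERYL_LINOLEATE] / sum(coef.values())
            assert frac == pytest.approx(best, abs=0.011)

    def test_axis_mismatch_rejected(self, ch_library, fp_axis):
        spec = Spectrum(fp_axis.values(), np.ones(fp_axis.n_channels))
        with pytest.raises(ValueError, match="axis"):
            decompose_spectrum(spec, ch_library)


class TestDetectBand:
    def test_linoleate_unsaturation_band_present(self, ch_axis):
        spec = synth_reference_spectrum(Species.CHOLESTERYL_LINOLEATE, ch_axis)
        present, peak, prom = detect_band(spec, BandWindow(3010.0, 20.0, 0.12))
        assert present
        assert abs(peak - 3010.0) <= 5.0

    def test_protein_has_no_band_near_3010(self, ch_axis):
        spec = synth_reference_spectrum(Species.PROTEIN, ch_axis)
        present, _, prom = detect_band(spec, BandWindow(3010.0, 20.0, 0.12))
        assert not present
        assert prom < 0.12

    def test_monotone_trace_has_no_interior_peak(self):
        w = np.arange(2900.0, 3061.0, 5.0)
        spec = Spectrum(w, np.linspace(1.0, 0.0, len(w)))
        present, peak, _ = detect_band(spec, BandWindow(3010.0, 20.0, 0.12))
        assert not present
        assert peak is None

    def test_window_outside_axis_rejected(self, fp_axis):
        spec = Spectrum(fp_axis.values(), np.ones(fp_axis.n_channels))
        with pytest.raises(ValueError, match="outside"):
            detect_band(spec, BandWindow(3010.0, 20.0, 0.12))


class TestClassifyComposition:
    def test_pure_linoleate_called_ce_with_unsaturation_flag(self, ch_library):
        rng = np.random.default_rng(0)
        y = ch_library.entries[Species.CHOLESTERYL_LINOLEATE].intensities.copy()
        y = np.clip(y + rng.normal(0, 0.05, len(y)), 0, None)  # SNR 20
        call = classify_composition(Spectrum(ch_library.wavenumbers_cm1, y), ch_library)
        assert call.dominant_class is DominantClass.CE_DOMINANT
        assert call.unsaturation_band_present is True
        assert call.ester_band_present is None

    def test_pure_monohydrate_on_fingerprint_axis(self, fp_library):
        y = fp_library.entries[Species.CHOLESTEROL_MONOHYDRATE].intensities
        call = classify_composition(Spectrum(fp_library.wavenumbers_cm1, y), fp_library)
        assert call.dominant_class is DominantClass.FREE_CHOLESTEROL
        assert call.ester_band_present is False
        assert call.unsaturation_band_present is None

    def test_equal_ce_mixture_pools_to_ce_dominant(self, ch_library):
        A = ch_library.matrix()
        sps = ch_library.species
        y = 0.5 * A[:, sps.index(Species.CHOLESTERYL_OLEATE)] + 0.5 * A[
            :, sps.index(Species.CHOLESTERYL_LINOLEATE)
        ]
        call = classify_composition(Spectrum(ch_library.wavenumbers_cm1, y), ch_library)
        assert call.dominant_class is DominantClass.CE_DOMINANT

    @pytest.mark.parametrize("scale", [0.01, 1.0, 250.0])
    def test_positive_scaling_leaves_call_invariant(self, ch_library, scale):
        rng = np.random.default_rng(5)
        y = ch_library.entries[Species.PROTEIN].intensities + rng.normal(0, 0.03, 51)
        y = np.clip(y, 0, None)
        base = classify_composition(Spectrum(ch_library.wavenumbers_cm1, y), ch_library)
        scaled = classify_composition(
            Spectrum(ch_library.wavenumbers_cm1, scale * y), ch_library
        )
        assert scaled.dominant_class is base.dominant_class
        assert scaled.unsaturation_band_present == base.unsaturation_band_present
        for sp in base.fractions:
            assert scaled.fractions[sp] == pytest.approx(base.fractions[sp], abs=1e-9)

    def test_axis_covering_no_diagnostic_region_rejected(self, ch_library):
        axis = WavenumberAxis(2400.0, 2600.0, 5.0)
        spec = Spectrum(axis.values(), np.ones(axis.n_channels))
        with pytest.raises(ValueError, match="diagnostic"):
            classify_composition(spec, ch_library)
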