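"""Background subtraction, sub-pixel Gaussian peak fitting, spacing shifts."""

import numpy as np
import pytest

from actinmech.simulate import PeakSimParams, generate_peak_profile
from actinmech.xray import (
    Calibration,
    IntensityProfile,
    PeakFitError,
    fit_gaussian_peak,
    intensity_fold_change,
    peak_asymmetry,
    spacing_percent_shift,
    subtract_background,
)

CAL = Calibration(centre_px=-900.0)


class TestSubtractBackground:
    def test_pure_ramp_vanishes(self):
        x = np.arange(100.0)
        prof = IntensityProfile(x, 3.0 + 0.5 * x)
        out = subtract_background(prof, (0, 19), (80, 99))
        assert np.max(np.abs(out.intensity)) < 1e-9

    def test_gaussian_on_ramp_recovered(self):
        p = PeakSimParams(centre=100.0, sigma=5.0, amplitude=50.0,
                          slope=0.3, intercept=7.0)
        prof = subtract_background(
            generate_peak_profile(p), (30, 60), (140, 170)
        )
        pure = generate_peak_profile(
            PeakSimParams(centre=100.0, sigma=5.0, amplitude=50.0)
        )
        np.testing.assert_allclose(prof.intensity, pure.intensity, atol=1e-6)

    def test_flat_zero_profile_unchanged(self):
        prof = IntensityProfile(np.arange(50.0), np.zeros(50))
        out = subtract_background(prof, (0, 9), (40, 49))
        np.testing.assert_allclose(out.intensity, 0.0, atol=1e-12)

    def test_flank_overlapping_peak_window_rejected(self):
        prof = IntensityProfile(np.arange(50.0), np.zeros(50))
        with pytest.raises(ValueError, match="overlap"):
            subtract_background(prof, (0, 25), (40, 49), peak_window=(20, 30))


class TestGaussianPeakFit:
    def test_noise_free_sub_pixel_recovery(self):
        prof = generate_peak_profile(PeakSimParams(centre=100.30, sigma=5.0))
        assert abs(fit_gaussian_peak(prof, w=4).mu - 100.30) < 0.01

    def test_integer_centre_exact_by_symmetry(self):
        prof = generate_peak_profile(PeakSimParams(centre=100.0, sigma=5.0))
        assert fit_gaussian_peak(prof, w=4).mu == pytest.approx(100.0, abs=1e-6)

    def test_translation_equivariance(self):
        p = PeakSimParams(centre=100.30, sigma=5.0, amplitude=10.0)
        prof = generate_peak_profile(p)
        shifted = IntensityProfile(prof.pixel + 17, prof.intensity)
        assert fit_gaussian_peak(shifted, w=4).mu == pytest.approx(
            fit_gaussian_peak(prof, w=4).mu + 17, abs=1e-9
        )

    def test_symmetric_peak_window_insensitive(self):
        prof = generate_peak_profile(PeakSimParams(centre=100.30, sigma=5.0))
        f3, f4 = fit_gaussian_peak(prof, w=3), fit_gaussian_peak(prof, w=4)
        assert abs(f3.mu - f4.mu) < 0.02

    def test_two_population_window_ordering(self):
        """A broad secondary component drags the wider-window centre further
        from the main component — the window-sensitivity diagnostic."""
        prof = generate_peak_profile(
            PeakSimParams(centre=100.0, sigma=5.0, amplitude=1.0,
                          second=(100.9, 9.0, 0.7))
        )
        f3, f4 = fit_gaussian_peak(prof, w=3), fit_gaussian_peak(prof, w=4)
        assert abs(f3.mu - 100.0) < abs(f4.mu - 100.0)

    def test_noisy_median_error_near_information_bound(self):
        # CRLB for sigma=5 px, 2% noise, w=4 gives sd(mu) ~ 0.081 px,
        # i.e. a median error of ~0.055 px; an efficient fit stays close.
        errs = []
        for seed in range(60):
            prof = generate_peak_profile(
                PeakSimParams(centre=100.30, sigma=5.0, amplitude=1.0,
                              noise_sd=0.02, seed=seed)
            )
            errs.append(abs(fit_gaussian_peak(prof, w=4).mu - 100.30))
        assert np.median(errs) < 0.08

    def test_featureless_profile_rejected(self):
        prof = IntensityProfile(np.arange(30.0), np.ones(30))
        with pytest.raises((PeakFitError, ValueError)):
            fit_gaussian_peak(prof, w=3)

    def test_window_outside_profile_rejected(self):
        prof = generate_peak_profile(PeakSimParams(n_pixels=10, centre=2.0,
                                                   sigma=1.0))
        with pytest.raises(ValueError):
            fit_gaussian_peak(prof, w=4)


class TestSpacingShift:
    def test_identical_fits_give_zero(self):
        prof = generate_peak_profile(PeakSimParams(centre=100.0, sigma=5.0))
        fit = fit_gaussian_peak(prof, w=4)
        assert spacing_percent_shift(fit, fit, CAL).percent == 0.0

    def test_radial_arithmetic(self):
        # R_rest = 1000.0, R_act = 998.2 -> +0.180 %
        rest = generate_peak_profile(PeakSimParams(centre=100.0, sigma=5.0))
        act = generate_peak_profile(PeakSimParams(centre=98.2, sigma=5.0))
        shift = spacing_percent_shift(
            fit_gaussian_peak(rest, w=4), fit_gaussian_peak(act, w=4), CAL
        )
        assert shift.r_rest == pytest.approx(1000.0, abs=1e-3)
        assert shift.r_act == pytest.approx(998.2, abs=1e-3)
        assert shift.percent == pytest.approx((1000.0 / 998.2 - 1) * 100, abs=1e-3)

    def test_condition_swap_flips_sign(self):
        rest = fit_gaussian_peak(
            generate_peak_profile(PeakSimParams(centre=100.0, sigma=5.0)), w=4
        )
        act = fit_gaussian_peak(
            generate_peak_profile(PeakSimParams(centre=98.2, sigma=5.0)), w=4
        )
        fwd = spacing_percent_shift(rest, act, CAL).percent
        rev = spacing_percent_shift(act, rest, CAL).percent
        assert fwd == pytest.approx(-rev, rel=5e-3)

    def test_missing_calibration_rejected(self):
        prof = generate_peak_profile(PeakSimParams(centre=100.0, sigma=5.0))
        fit = fit_gaussian_peak(prof, w=4)
        with pytest.raises(ValueError):
            spacing_percent_shift(fit, fit, None)


class TestAsymmetry:
    def test_symmetric_peak_scores_zero(self):
        prof = generate_peak_profile(PeakSimParams(centre=100.0, sigma=5.0))
        fit = fit_gaussian_peak(prof, w=4)
        score = peak_asymmetry(prof, fit)
        assert abs(score.skew) < 1e-6

    def test_two_population_composite_scores_nonzero(self):
        prof = generate_peak_profile(
            PeakSimParams(centre=100.0, sigma=5.0, amplitude=1.0,
                          second=(100.9, 9.0, 0.7))
        )
        fit = fit_gaussian_peak(prof, w=4)
        score = peak_asymmetry(prof, fit)
        assert abs(score.skew) > 1e-3
        assert abs(score.half_area_imbalance) > 1e-3

    def test_mirrored_profile_negates_score(self):
        prof = generate_peak_profile(
            PeakSimParams(centre=100.0, sigma=5.0, amplitude=1.0,
                          second=(100.9, 9.0, 0.7))
        )
        fit = fit_gaussian_peak(prof, w=4)
        mirrored = IntensityProfile(prof.pixel, prof.intensity[::-1].copy())
        fit_m = fit_gaussian_peak(mirrored, w=4)
        assert peak_asymmetry(mirrored, fit_m).skew == pytest.approx(
            -peak_asymmetry(prof, fit).skew, abs=1e-6
        )


class TestFoldChange:
    def test_identical_profiles_fold_one(self):
        prof = generate_peak_profile(PeakSimParams(centre=100.0, sigma=5.0))
        assert intensity_fold_change(prof, prof, (90, 110)).fold == 1.0

    def test_doubled_intensity_fold_two(self):
        prof = generate_peak_profile(PeakSimParams(centre=100.0, sigma=5.0))
        doubled = IntensityProfile(prof.pixel, 2.0 * prof.intensity)
        assert intensity_fold_change(prof, doubled, (90, 110)).fold == pytest.approx(2.0)

    def test_amplitude_ratio_recovered_under_noise(self):
        folds = []
        for seed in range(20):
            a = generate_peak_profile(
                PeakSimParams(centre=100.0, sigma=8.0, amplitude=1000.0,
                              noise_sd=10.0, seed=seed)
            )
            b = generate_peak_profile(
                PeakSimParams(centre=100.0, sigma=8.0, amplitude=1600.0,
                              noise_sd=10.0, seed=1000 + seed)
            )
            folds.append(intensity_fold_change(a, b, (80, 120)).fold)
        assert np.median(folds) == pytest.approx(1.6, abs=0.02)

    def test_nonpositive_reference_rejected(self):
        x = np.arange(50.0)
        zero = IntensityProfile(x, np.zeros(50))
        peak = IntensityProfile(x, np.exp(-((x - 25) ** 2) / 8))
        with pytest.raises(ValueError):
            intensity_fold_change(zero, peak, (10, 40))
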