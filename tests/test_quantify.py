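"""Peak integration, metabolite/ratio maps, ROI fitting and tables."""

import dataclasses

import numpy as np
import pytest

from hpcsi.acquisition import AcquisitionParams
from hpcsi.kinetics import KineticParams
from hpcsi.peaks import ALANINE, BICARBONATE, LACTATE, PYRUVATE, MetabolitePeak
from hpcsi.phantom import LABELS, PhantomSpec, build_phantom, roi_masks
from hpcsi.quantify import (
    average_roi_spectrum,
    compute_metabolite_maps,
    compute_ratio_maps,
    fit_peak_gaussian,
    integrate_peak,
    quantify_rois,
    ratio_table,
)
from hpcsi.recon import SpectralImage, phase_correct, reconstruct
from hpcsi.simulate import synthesize_kspace


class TestIntegratePeak:
    def test_zero_spectrum_integrates_to_zero(self):
        f = np.arange(-2500, 2500, 2.0)
        assert integrate_peak(np.zeros_like(f), f, 0.0, 44.0) == 0.0

    def test_lorentzian_capture_fraction_matches_closed_form(self):
        """A 44 Hz window captures (2/pi)*arctan(44/20) of a centered
        unit-area 20 Hz Lorentzian."""
        f = np.arange(-2500, 2500, 0.2)
        lor = (1 / np.pi) * 10.0 / (f**2 + 100.0)
        captured = integrate_peak(lor, f, 0.0, 44.0)
        expected = (2 / np.pi) * np.arctan(44.0 / 20.0)
        assert captured == pytest.approx(expected, rel=5e-3)

    def test_area_is_linear_in_amplitude(self):
        f = np.arange(-500, 500, 1.0)
        spec = np.exp(-(f**2) / 800.0)
        assert integrate_peak(2 * spec, f, 0.0, 44.0) == pytest.approx(
            2 * integrate_peak(spec, f, 0.0, 44.0)
        )

    def test_window_off_axis_rejected(self):
        f = np.arange(-100, 100, 1.0)
        with pytest.raises(ValueError, match="beyond the frequency axis"):
            integrate_peak(np.ones_like(f), f, 90.0, 44.0)

    def test_window_narrower_than_bin_rejected(self):
        f = np.arange(-2500, 2500, 50.0)
        with pytest.raises(ValueError, match="bin width"):
            integrate_peak(np.ones_like(f), f, 0.0, 44.0)


class TestMetaboliteMaps:
    def test_default_grid_is_32_by_32(self, noiseless_image):
        maps = compute_metabolite_maps(noiseless_image)
        for m in maps.maps.values():
            assert m.shape == (32, 32)
        assert maps.window_hz == 44.0

    def test_unphased_image_rejected(self, noiseless_kspace):
        img = reconstruct(noiseless_kspace)
        with pytest.raises(ValueError, match="phased"):
            compute_metabolite_maps(img)

    def test_overlapping_windows_error_names_the_pair(self, noiseless_image):
        close = (
            PYRUVATE,
            MetabolitePeak("lactate", 171.5),  # 16 Hz from the carrier
        )
        with pytest.raises(ValueError, match="pyruvate.*lactate|lactate.*pyruvate"):
            compute_metabolite_maps(noiseless_image, peaks=close)

    def test_lactate_confined_to_producing_hemisphere(self, cfg):
        """With lactate conversion only in one hemisphere, the Lac map
        support stays in that hemisphere up to 1 voxel of point spread."""
        from scipy.ndimage import binary_dilation

        kin = {
            LABELS["brain_ipsi"]: KineticParams(k_pl=0.02),
            LABELS["brain_contra"]: KineticParams(),
            LABELS["muscle"]: KineticParams(),
            LABELS["vessel"]: KineticParams(),
        }
        phantom = build_phantom(PhantomSpec(kinetics_by_label=kin))
        img = phase_correct(reconstruct(synthesize_kspace(phantom, AcquisitionParams())))
        lac = compute_metabolite_maps(img).maps["lactate"]
        # native-resolution producing region, upsampled and dilated 1 voxel
        producing = np.kron(
            phantom.label_map == LABELS["brain_ipsi"], np.ones((2, 2), bool)
        )
        # tolerance: one native voxel plus the Hanning PSF half-width
        allowed = binary_dilation(producing, iterations=3)
        strong = lac > 0.1 * lac.max()
        assert not (strong & ~allowed).any()

    def test_all_zero_spectra_give_zero_maps(self):
        freq = np.linspace(-2500, 2497.5, 2048)
        img = SpectralImage(
            np.zeros((8, 8, 2048), complex), freq, freq / 32.13 + 171.0, phased=True
        )
        maps = compute_metabolite_maps(img)
        for m in maps.maps.values():
            assert np.all(m == 0)


class TestRatioMaps:
    def test_ratios_invariant_under_global_scaling(self, noiseless_image, injured_rois):
        maps = compute_metabolite_maps(noiseless_image)
        scaled = dataclasses.replace(
            maps, maps={k: 10.0 * v for k, v in maps.maps.items()}
        )
        r1 = compute_ratio_maps(maps, injured_rois["brain"], floor=1e-9)
        r2 = compute_ratio_maps(scaled, injured_rois["brain"], floor=1e-8)
        np.testing.assert_allclose(
            r1["bic_pyr"][injured_rois["brain"]],
            r2["bic_pyr"][injured_rois["brain"]],
            rtol=1e-12,
        )

    def test_low_denominator_voxels_are_undefined_not_zero(
        self, noiseless_image, injured_rois
    ):
        maps = compute_metabolite_maps(noiseless_image)
        huge_floor = 10 * maps.maps["pyruvate"].max()
        ratios = compute_ratio_maps(maps, injured_rois["brain"], floor=huge_floor)
        assert np.all(np.isnan(ratios["bic_pyr"]))

    def test_empty_mask_rejected(self, noiseless_image):
        maps = compute_metabolite_maps(noiseless_image)
        with pytest.raises(ValueError, match="empty"):
            compute_ratio_maps(maps, np.zeros((32, 32), bool))

    def test_lesion_lowers_bic_pyr_against_mirror(self, injured_image, injured_rois):
        maps = compute_metabolite_maps(injured_image)
        ratios = compute_ratio_maps(maps, injured_rois["brain"], floor=1e-9)
        bic_pyr = ratios["bic_pyr"]
        assert np.nanmean(bic_pyr[injured_rois["ipsi"]]) < np.nanmean(
            bic_pyr[injured_rois["contra"]]
        )


class TestRoiSpectrum:
    def test_single_voxel_roi_returns_that_voxel(self, noiseless_image):
        roi = np.zeros((32, 32), bool)
        roi[16, 16] = True
        np.testing.assert_array_equal(
            average_roi_spectrum(noiseless_image, roi),
            noiseless_image.spectra[16, 16],
        )

    def test_mean_is_linear(self, noiseless_image, injured_rois):
        roi = injured_rois["contra"]
        doubled = SpectralImage(
            2 * noiseless_image.spectra,
            noiseless_image.freq_hz,
            noiseless_image.ppm,
            phased=True,
        )
        np.testing.assert_allclose(
            average_roi_spectrum(doubled, roi),
            2 * average_roi_spectrum(noiseless_image, roi),
        )

    def test_empty_roi_rejected(self, noiseless_image):
        with pytest.raises(ValueError, match="empty"):
            average_roi_spectrum(noiseless_image, np.zeros((32, 32), bool))

    def test_averaging_reduces_noise_like_sqrt_n(self, rng):
        """Complex mean over N voxels of i.i.d. noise has SD sigma/sqrt(N)."""
        n_vox = 16
        sds = []
        for _ in range(200):
            spectra = rng.standard_normal((4, 4, 64)) + 1j * rng.standard_normal(
                (4, 4, 64)
            )
            freq = np.linspace(-100, 100, 64)
            img = SpectralImage(spectra, freq, freq / 32.13 + 171.0)
            avg = average_roi_spectrum(img, np.ones((4, 4), bool))
            sds.append(np.std(avg.real))
        assert np.mean(sds) == pytest.approx(1 / np.sqrt(n_vox), rel=0.05)


class TestGaussianFit:
    def test_exact_gaussian_recovered_to_machine_precision(self):
        f = np.linspace(-150, 150, 1201)
        y = 5.0 * np.exp(-(f**2) / (2 * 10.0**2))
        fit = fit_peak_gaussian(y, f, 0.0, search_window=120, noise_sd=1e-9)
        assert fit.amplitude == pytest.approx(5.0, rel=1e-6)
        assert fit.sigma == pytest.approx(10.0, rel=1e-6)
        assert fit.center == pytest.approx(0.0, abs=1e-6)
        assert fit.area == pytest.approx(5 * 10 * np.sqrt(2 * np.pi), rel=1e-6)
        assert not fit.rejected

    def test_area_recovered_within_5pc_at_snr_20(self, rng):
        """Monte-Carlo: median area error < 5% over 50 noisy realizations."""
        f = np.linspace(-150, 150, 600)
        truth = 20.0 * np.exp(-(f**2) / (2 * 12.0**2))
        true_area = 20.0 * 12.0 * np.sqrt(2 * np.pi)
        errors = []
        for _ in range(50):
            y = truth + rng.standard_normal(f.size)  # amplitude SNR 20
            fit = fit_peak_gaussian(y, f, 0.0, search_window=120, noise_sd=1.0)
            errors.append(abs(fit.area - true_area) / true_area)
        assert np.median(errors) < 0.05

    def test_pure_noise_window_is_rejected(self, rng):
        f = np.linspace(-150, 150, 600)
        y = rng.standard_normal(f.size)
        fit = fit_peak_gaussian(y, f, 0.0, search_window=120, noise_sd=1.0)
        assert fit.rejected and np.isnan(fit.area)


class TestQuantifyRois:
    def test_missing_required_roi_rejected(self, noiseless_image, injured_rois):
        rois = {k: v for k, v in injured_rois.items() if k != "muscle"}
        with pytest.raises(ValueError, match="muscle"):
            quantify_rois(noiseless_image, rois)

    def test_recovered_ratio_consistent_with_truth_at_snr_30(
        self, cfg, injured_phantom, injured_image, injured_rois
    ):
        """Bic/Pyr estimated at the cohort SNR is consistent (median over
        noise realizations) with the deterministic forward-model value to
        within 10%."""
        from hpcsi.simulate import calibrate_noise_sigma

        rois = {k: injured_rois[k] for k in ("ipsi", "contra", "muscle")}
        truth = ratio_table(quantify_rois(injured_image, rois)).set_index("roi")
        acq = AcquisitionParams()
        sigma = calibrate_noise_sigma(injured_phantom, acq, cfg.cohort.target_snr)
        values = []
        for seed in range(6):
            noisy_acq = dataclasses.replace(acq, noise_sigma=sigma, seed=seed)
            img = phase_correct(
                reconstruct(synthesize_kspace(injured_phantom, noisy_acq))
            )
            wide = ratio_table(quantify_rois(img, rois)).set_index("roi")
            values.append(wide.loc["contra", "bic_pyr"])
        assert np.median(values) == pytest.approx(
            truth.loc["contra", "bic_pyr"], rel=0.10
        )

    def test_map_and_fit_quantification_agree(self, injured_image, injured_rois):
        """The two Bic/Pyr estimators (windowed map integrals vs Gaussian
        fits of the ROI spectrum) agree within 15% for isolated peaks."""
        maps = compute_metabolite_maps(injured_image)
        roi = injured_rois["contra"]
        map_ratio = maps.maps["bicarbonate"][roi].sum() / maps.maps["pyruvate"][roi].sum()
        rois = {k: injured_rois[k] for k in ("ipsi", "contra", "muscle")}
        fits = ratio_table(quantify_rois(injured_image, rois)).set_index("roi")
        assert map_ratio == pytest.approx(fits.loc["contra", "bic_pyr"], rel=0.15)

    def test_absent_brain_alanine_is_flagged_rejected(self, cfg):
        kin = {
            LABELS["brain_ipsi"]: KineticParams(k_pl=0.02, k_pb=0.006),
            LABELS["brain_contra"]: KineticParams(k_pl=0.02, k_pb=0.006),
            LABELS["muscle"]: KineticParams(k_pl=0.01),  # no alanine anywhere
            LABELS["vessel"]: KineticParams(perfusion_scale=3.0),
        }
        phantom = build_phantom(PhantomSpec(kinetics_by_label=kin))
        acq = AcquisitionParams(noise_sigma=4.0, seed=1)
        img = phase_correct(reconstruct(synthesize_kspace(phantom, acq)))
        rois = roi_masks(phantom, upsample=2)
        quant = quantify_rois(
            img, {k: rois[k] for k in ("ipsi", "contra", "muscle")}
        )
        brain_ala = quant[
            (quant.roi.isin(["ipsi", "contra"])) & (quant.metabolite == "alanine")
        ]
        assert brain_ala.rejected.all()

    def test_bic_pyr_increases_with_kpb_noise_free(self, cfg):
        """Recovered Bic/Pyr is strictly monotone over a k_PB grid."""
        recovered = []
        for k_pb in np.linspace(0.003, 0.012, 5):
            kin = {
                LABELS["brain_ipsi"]: KineticParams(k_pl=0.02, k_pb=k_pb),
                LABELS["brain_contra"]: KineticParams(k_pl=0.02, k_pb=k_pb),
                LABELS["muscle"]: KineticParams(k_pl=0.01, k_pb=0.002, k_pa=0.01),
                LABELS["vessel"]: KineticParams(perfusion_scale=3.0),
            }
            phantom = build_phantom(PhantomSpec(kinetics_by_label=kin))
            img = phase_correct(
                reconstruct(synthesize_kspace(phantom, AcquisitionParams()))
            )
            rois = roi_masks(phantom, upsample=2)
            wide = ratio_table(
                quantify_rois(img, {k: rois[k] for k in ("ipsi", "contra", "muscle")})
            ).set_index("roi")
            recovered.append(wide.loc["contra", "bic_pyr"])
        assert np.all(np.diff(recovered) > 0)

    def test_ratio_metrics_invariant_to_receive_gain(
        self, injured_image, injured_rois
    ):
        rois = {k: injured_rois[k] for k in ("ipsi", "contra", "muscle")}
        base = ratio_table(quantify_rois(injured_image, rois)).set_index("roi")
        gained = SpectralImage(
            37.0 * injured_image.spectra,
            injured_image.freq_hz,
            injured_image.ppm,
            phased=True,
            provenance=injured_image.provenance,
        )
        scaled = ratio_table(quantify_rois(gained, rois)).set_index("roi")
        for metric in ("lac_pyr", "bic_pyr", "bic_lac", "ala_pyr"):
            assert scaled.loc["contra", metric] == pytest.approx(
                base.loc["contra", metric], rel=1e-6
            )
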