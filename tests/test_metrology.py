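"""Transducer and image metrology: k_eff, spectra, crosstalk, FWHM, CNR."""

import math

import numpy as np
import pytest

from trimodal.benchmarks import synthesize_impedance
from trimodal.forward import (AcquisitionSpec, TransducerSpec,
                              pa_channel_data)
from trimodal.metrology import (DetectionError, ImpedanceSpectrum, PulseEcho,
                                cnr, crosstalk_db, fold_change, fwhm,
                                keff_from_frequencies, keff_from_impedance,
                                pulse_echo_metrics, pulsation_spectrum)
from trimodal.phantom import GridSpec, raised_cosine_train
from trimodal.recon import ImageGrid, das_pa, envelope

from conftest import point_phantom


class TestKeff:
    def test_printed_resonance_pair_gives_half(self):
        assert round(keff_from_frequencies(6.53, 7.54), 2) == 0.50

    def test_equal_frequencies_give_zero(self):
        assert keff_from_frequencies(7.0, 7.0) == 0.0

    def test_synthetic_resonator_recovered(self):
        spec = synthesize_impedance(5.0, 6.0)
        f_r, f_a, keff = keff_from_impedance(spec)
        assert keff == pytest.approx(math.sqrt(1 - 25 / 36), abs=1e-3)
        assert f_r == pytest.approx(5.0, abs=0.01)
        assert f_a == pytest.approx(6.0, abs=0.01)

    @pytest.mark.parametrize("scale", [0.1, 1.0, 250.0])
    def test_invariant_to_magnitude_scale(self, scale):
        spec = synthesize_impedance(6.53, 7.54)
        scaled = ImpedanceSpectrum(spec.freqs_mhz,
                                   scale * spec.magnitude_ohm)
        assert keff_from_impedance(scaled)[2] == pytest.approx(
            keff_from_impedance(spec)[2])

    def test_monotone_spectrum_rejected(self):
        f = np.linspace(4, 10, 64)
        with pytest.raises(DetectionError):
            keff_from_impedance(ImpedanceSpectrum(f, np.linspace(2, 1, 64)))


class TestPulseEcho:
    def _echo(self, fc=7.0, frac_bw=0.45, fs=100.0, noise=0.0, seed=0):
        tx = TransducerSpec(center_freq_mhz=fc, frac_bandwidth=frac_bw)
        t = np.arange(4096) / fs
        tau = 12.0
        w = np.cos(2 * np.pi * fc * (t - tau)) * np.exp(
            -0.5 * ((t - tau) / tx.pulse_sigma_us) ** 2)
        rng = np.random.default_rng(seed)
        return PulseEcho(w + noise * rng.normal(size=t.size), fs)

    def test_gaussian_pulse_spectral_summary(self):
        """A 7 MHz pulse built for 45% -6 dB bandwidth reads back as such."""
        center, bw, _ = pulse_echo_metrics(self._echo())
        assert center == pytest.approx(7.0, rel=0.01)
        assert bw == pytest.approx(0.45, rel=0.01)

    def test_snr_estimate_tracks_noise_level(self):
        _, _, snr = pulse_echo_metrics(self._echo(noise=1e-2))
        assert 30.0 < snr < 50.0

    def test_pure_tone_hits_spectral_resolution_floor(self):
        fs = 100.0
        t = np.arange(4096) / fs
        pe = PulseEcho(np.cos(2 * np.pi * 7.0 * t), fs)
        _, bw, _ = pulse_echo_metrics(pe)
        df = fs / 4096
        assert bw * 7.0 < 6 * df  # bandwidth collapsed to the bin width


class TestCrosstalk:
    @pytest.fixture()
    def drive(self):
        t = np.arange(2048) / 50.0
        return np.sin(2 * np.pi * 5 * t) + 0.4 * np.sin(2 * np.pi * 7 * t)

    def test_tenth_amplitude_neighbor(self, drive):
        res = crosstalk_db(drive, [0.1 * drive], fs_mhz=50.0)
        assert res["orders"][0]["crosstalk_db"] == pytest.approx(-20.0)
        assert not res["orders"][0]["passes"]  # louder than the -30 dB limit

    def test_quiet_neighbor_passes_threshold(self, drive):
        res = crosstalk_db(drive, [0.017 * drive], fs_mhz=50.0)
        assert res["orders"][0]["passes"]

    def test_equal_signal_zero_db(self, drive):
        res = crosstalk_db(drive, [drive], fs_mhz=50.0)
        assert res["orders"][0]["crosstalk_db"] == pytest.approx(0.0)
        assert not res["orders"][0]["passes"]

    def test_coupling_chain_closed_form(self, drive):
        """Per-order factor 0.017 -> -35.4 dB, squared -> -70.9 dB."""
        res = crosstalk_db(drive, [0.017 * drive, 0.017 ** 2 * drive], 50.0)
        assert res["orders"][0]["crosstalk_db"] == pytest.approx(
            20 * math.log10(0.017), abs=0.01)
        assert res["orders"][1]["crosstalk_db"] == pytest.approx(
            40 * math.log10(0.017), abs=0.01)

    def test_zero_drive_rejected(self, drive):
        with pytest.raises(ValueError):
            crosstalk_db(np.zeros_like(drive), [drive], 50.0)

    def test_band_beyond_nyquist_rejected(self, drive):
        with pytest.raises(ValueError):
            crosstalk_db(drive, [drive], fs_mhz=10.0, band_mhz=(1.0, 9.0))


class TestFWHM:
    def test_gaussian_closed_form(self):
        x = np.arange(-6, 6, 0.01)
        assert fwhm(np.exp(-0.5 * x ** 2), 0.01) == pytest.approx(
            2.3548, rel=1e-3)

    def test_triangle(self):
        x = np.arange(-2, 2, 0.01)
        assert fwhm(np.maximum(0, 1 - np.abs(x)), 0.01) == pytest.approx(
            1.0, abs=1e-3)

    def test_boundary_peak_rejected(self):
        with pytest.raises(DetectionError):
            fwhm(np.arange(10.0), 0.1)

    def test_point_target_profile_estimator(self, tx, quiet_acq):
        """FWHM of a simulated point-target PA profile is finite and ~mm."""
        grid = GridSpec((64, 1, 160), 0.125)
        p = point_phantom(grid, [(0.0, 12.0)])
        cd = pa_channel_data(p, np.ones(grid.shape), tx, quiet_acq, 796.0)
        igrid = ImageGrid(8.0, 20.0, 0.1)
        env = envelope(das_pa(cd, tx, igrid)).pixels
        pz, _ = np.unravel_index(np.argmax(env), env.shape)
        width = fwhm(env[pz], 0.1)
        assert 0.1 < width < 1.0


class TestCNR:
    def test_identical_rois_zero(self):
        rng = np.random.default_rng(0)
        half = rng.uniform(1, 2, (10, 20))
        img = np.vstack([half, half])  # both ROIs carry identical samples
        t = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        t[:10] = True
        b[10:] = True
        assert cnr(img, t, b) == pytest.approx(0.0, abs=1e-12)

    def test_direct_formula_case(self):
        img = np.zeros((10, 10))
        t = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        t[:5], b[5:] = True, True
        img[t] = 10.0
        img[b] = np.tile([4.0, 6.0], 25)  # mean 5, std 1
        assert cnr(img, t, b) == pytest.approx(5.0)

    def test_matches_brute_force_over_roi_pixels(self):
        rng = np.random.default_rng(2)
        img = rng.rayleigh(1.0, (40, 40))
        yy, xx = np.mgrid[:40, :40]
        t = (yy - 20) ** 2 + (xx - 20) ** 2 <= 36
        b = (yy - 20) ** 2 + (xx - 20) ** 2 >= 225
        img[t] *= 0.2  # anechoic disk in speckle
        tv, bv = img[t], img[b]
        manual = abs(tv.mean() - bv.mean()) / math.sqrt(tv.var() + bv.var())
        assert cnr(img, t, b) == pytest.approx(manual, rel=1e-12)

    def test_small_roi_rejected(self):
        img = np.ones((10, 10))
        t = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        t[0, :3], b[5:] = True, True
        with pytest.raises(ValueError):
            cnr(img, t, b)


class TestPulsation:
    def test_constant_series_flagged_no_peak(self):
        res = pulsation_spectrum(np.ones(128), 20.0)
        assert res["no_peak"] and res["fundamental_hz"] is None

    def test_noiseless_fundamental_within_one_bin(self):
        t = np.arange(200) / 20.0
        series = raised_cosine_train(1.4 * t)
        res = pulsation_spectrum(series, 20.0)
        assert res["fundamental_hz"] == pytest.approx(1.4, abs=0.1)

    def test_noisy_pulse_train_recovery_with_harmonics(self):
        rng = np.random.default_rng(0)
        t = np.arange(200) / 20.0
        series = 1 + 0.2 * raised_cosine_train(1.4 * t) \
            + 0.02 * rng.normal(size=200)
        res = pulsation_spectrum(series, 20.0, expected_fundamental_hz=1.4)
        assert res["fundamental_hz"] == pytest.approx(1.4, abs=0.1)
        assert len(res["harmonics_hz"]) >= 2

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            pulsation_spectrum(np.ones(32), 20.0)


class TestFoldChange:
    def test_equal_means_unity(self):
        assert fold_change(3.3, 3.3) == 1.0

    def test_eleven_fold(self):
        assert fold_change(0.5, 5.5) == pytest.approx(11.0)

    def test_nonpositive_pre_rejected(self):
        with pytest.raises(ValueError):
            fold_change(0.0, 1.0)

    def test_end_to_end_icg_enhancement_recovery(self, tx, spectra):
        """11x ICG amplification survives simulate -> recon -> unmix."""
        from trimodal.phantom import Background, VesselSpec, make_phantom
        from trimodal.spectral import SpectralStack, build_M, \
            fluence_compensate, unmix
        grid = GridSpec((64, 1, 64), 0.15)
        wavelengths = (690.0, 720.0, 756.0, 796.0)
        igrid = ImageGrid(grid.extent_mm[0], grid.extent_mm[2], 0.15)
        M = build_M(spectra, wavelengths, ["Hb", "HbO2", "ICG"])
        roi_means = []
        for conc in (1e-6, 11e-6):
            node = VesselSpec(np.array([[0.0, 0.0, 3.0], [1e-3, 0.0, 3.0]]),
                              0.5, {"ICG": conc})
            p = make_phantom([node], grid, Background(), seed=0)
            acq = AcquisitionSpec(wavelengths_nm=wavelengths, noise_rms=0.0,
                                  seed=0)
            images = []
            for wl in wavelengths:
                cd = pa_channel_data(p, np.ones(grid.shape), tx, acq, wl,
                                     spectra)
                images.append(envelope(das_pa(cd, tx, igrid)).pixels)
            stack = SpectralStack(np.stack(images), np.array(wavelengths),
                                  pixel_size_mm=0.15)
            maps = unmix(fluence_compensate(stack), M,
                         species=["Hb", "HbO2", "ICG"])
            X, Z = np.meshgrid(igrid.x_mm, igrid.z_mm, indexing="xy")
            roi = X ** 2 + (Z - 3.0) ** 2 <= 0.35 ** 2
            roi_means.append(float(maps.conc["ICG"][roi].mean()))
        assert fold_change(*roi_means) == pytest.approx(11.0, rel=0.15)
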