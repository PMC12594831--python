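"""Fluence compensation, pseudo-inverse unmixing and sO2 mapping."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from trimodal.pipeline import IN_VIVO_WAVELENGTHS
from trimodal.spectral import (DegeneracyError, SpectralStack, build_M,
                               fluence_compensate, so2_map, unmix)


def make_stack(images, wavelengths, compensated=False, px=0.15):
    return SpectralStack(images=np.asarray(images, dtype=float),
                         wavelengths_nm=np.asarray(wavelengths, dtype=float),
                         compensated=compensated, pixel_size_mm=px)


class TestFluenceCompensate:
    def test_depth_uniform_image_unchanged(self):
        img = np.full((60, 40), 3.0)
        out = fluence_compensate(make_stack([img], [756.0]))
        assert np.allclose(out.images[0] / img, 1.0, atol=1e-6)
        assert out.compensated

    def test_recovers_truth_under_exponential_decay(self):
        rng = np.random.default_rng(0)
        truth = 1.0 + 0.3 * gaussian_filter(rng.normal(size=(140, 80)), 3)
        z = (np.arange(140) + 0.5) * 0.15
        img = truth * np.exp(-0.2 * z)[:, None]
        out = fluence_compensate(make_stack([img], [756.0]))
        rel = np.abs(out.images[0] / truth - 1.0)
        assert rel[z <= 15.0].max() < 0.05

    def test_double_compensation_rejected(self):
        st = make_stack([np.ones((30, 30))], [756.0], compensated=True)
        with pytest.raises(ValueError, match="already"):
            fluence_compensate(st)

    def test_all_zero_stack_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            fluence_compensate(make_stack([np.zeros((30, 30))], [756.0]))

    def test_narrow_background_rows_warn_and_fall_back(self):
        img = np.ones((30, 30))
        mask = np.zeros((30, 30), dtype=bool)
        mask[10, :25] = True  # row 10 has too few background pixels
        with pytest.warns(UserWarning, match="background pixels"):
            out = fluence_compensate(make_stack([img], [756.0]),
                                     object_mask=mask)
        assert np.allclose(out.images[0], img, atol=1e-6)


class TestBuildM:
    def test_in_vivo_wavelengths_full_rank(self, spectra):
        M = build_M(spectra, IN_VIVO_WAVELENGTHS, ["Hb", "HbO2", "ICG"])
        assert M.shape == (3, 5)
        assert np.linalg.matrix_rank(M) == 3
        assert np.allclose(M.max(axis=1), 1.0)

    def test_single_species_row_is_normalized_spectrum(self, spectra):
        wl = [690.0, 756.0, 796.0]
        M = build_M(spectra, wl, ["ICG"])
        eps = np.array([spectra.epsilon("ICG", w) for w in wl])
        assert np.allclose(M[0], eps / eps.max())

    def test_isosbestic_equality_on_raw_coefficients(self, spectra):
        """Unnormalized Hb and HbO2 columns agree at the isosbestic point."""
        M = build_M(spectra, [690.0, 796.0, 866.0], ["Hb", "HbO2"],
                    normalize=False)
        assert M[0, 1] == pytest.approx(M[1, 1], rel=0.01)

    def test_duplicate_species_degenerate(self, spectra):
        with pytest.raises(DegeneracyError, match="Hb"):
            build_M(spectra, IN_VIVO_WAVELENGTHS, ["Hb", "Hb"])

    def test_fewer_wavelengths_than_species_rejected(self, spectra):
        with pytest.raises(ValueError):
            build_M(spectra, [756.0, 796.0], ["Hb", "HbO2", "ICG"])


@pytest.fixture(scope="module")
def M(spectra):
    return build_M(spectra, IN_VIVO_WAVELENGTHS, ["Hb", "HbO2", "ICG"])


class TestUnmix:

    def test_row_vector_recovers_unit_species(self, M):
        for n, s in enumerate(["Hb", "HbO2", "ICG"]):
            c = 2.7
            pa = c * M[n]
            stack = make_stack(pa.reshape(-1, 1, 1), IN_VIVO_WAVELENGTHS,
                               compensated=True)
            maps = unmix(stack, M, species=["Hb", "HbO2", "ICG"])
            assert maps.conc[s][0, 0] == pytest.approx(c, abs=1e-9)
            for other in set(maps.conc) - {s}:
                assert abs(maps.conc[other][0, 0]) < 1e-9

    def test_random_triplets_match_lstsq_oracle(self, M):
        rng = np.random.default_rng(42)
        C = rng.uniform(0, 1, size=(500, 3))
        PA = C @ M
        stack = make_stack(PA.T.reshape(5, 500, 1), IN_VIVO_WAVELENGTHS,
                           compensated=True)
        maps = unmix(stack, M, species=["Hb", "HbO2", "ICG"])
        rec = np.stack([maps.conc[s].ravel()
                        for s in ["Hb", "HbO2", "ICG"]], axis=1)
        assert np.abs((rec - C) / C).max() <= 1e-9
        oracle = np.linalg.lstsq(M.T, PA.T, rcond=None)[0].T
        assert np.abs(rec - oracle).max() <= 1e-9

    def test_icg_map_isolates_icg_tube(self, M):
        """Blood pixels stay out of the ICG map and vice versa."""
        blood = 0.3 * M[0] + 0.7 * M[1]
        icg = 1.0 * M[2]
        img = np.stack([np.array([[b, i]]) for b, i in zip(blood, icg)])
        stack = make_stack(img, IN_VIVO_WAVELENGTHS, compensated=True)
        maps = unmix(stack, M, species=["Hb", "HbO2", "ICG"])
        assert maps.conc["ICG"][0, 1] == pytest.approx(1.0, abs=1e-9)
        assert abs(maps.conc["ICG"][0, 0]) < 1e-9
        assert maps.conc["HbO2"][0, 0] == pytest.approx(0.7, abs=1e-9)

    def test_uncompensated_stack_rejected(self, M):
        stack = make_stack(np.zeros((5, 2, 2)), IN_VIVO_WAVELENGTHS)
        with pytest.raises(ValueError, match="compensated"):
            unmix(stack, M)

    def test_scale_invariance(self, M):
        rng = np.random.default_rng(1)
        C = rng.uniform(0.1, 1, size=(50, 3))
        PA = C @ M
        for scale in (1.0, 37.5):
            stack = make_stack(scale * PA.T.reshape(5, 50, 1),
                               IN_VIVO_WAVELENGTHS, compensated=True)
            maps = so2_map(unmix(stack, M, species=["Hb", "HbO2", "ICG"]),
                           total_hb_threshold=0.0)
            if scale == 1.0:
                base = maps.so2.data.copy()
            else:
                assert np.allclose(maps.so2.data, base)

    def test_adding_wavelength_never_hurts_noiseless_recovery(self, spectra):
        rng = np.random.default_rng(5)
        C = rng.uniform(0.1, 1, size=(200, 3))
        errs = []
        for wl in [IN_VIVO_WAVELENGTHS[:4], IN_VIVO_WAVELENGTHS]:
            M = build_M(spectra, wl, ["Hb", "HbO2", "ICG"])
            PA = C @ M
            stack = make_stack(PA.T.reshape(len(wl), 200, 1), wl,
                               compensated=True)
            maps = unmix(stack, M, species=["Hb", "HbO2", "ICG"])
            rec = np.stack([maps.conc[s].ravel()
                            for s in ["Hb", "HbO2", "ICG"]], axis=1)
            errs.append(np.abs(rec - C).max())
        assert errs[1] <= errs[0] + 1e-12

    def test_isosbestic_pixel_insensitive_to_hb_swap(self, spectra):
        """PA at 796 nm changes < 2% when Hb and HbO2 are swapped at sO2 0.5."""
        e_hb = spectra.epsilon("Hb", 796.0)
        e_hbo2 = spectra.epsilon("HbO2", 796.0)
        pa = 0.5 * e_hb + 0.5 * e_hbo2
        pa_swapped = 0.5 * e_hbo2 + 0.5 * e_hb
        assert abs(pa - pa_swapped) / pa < 0.02
        # even the per-species exchange is within 2% at the isosbestic point
        assert abs(e_hb - e_hbo2) / e_hb < 0.02


class TestSO2Map:
    def _maps(self, hb, hbo2):
        stack_like = {"Hb": np.array([[hb]]), "HbO2": np.array([[hbo2]])}
        from trimodal.spectral import UnmixedMaps
        return UnmixedMaps(conc=stack_like)

    def test_pure_hbo2_gives_unity(self):
        maps = so2_map(self._maps(0.0, 0.5), total_hb_threshold=0.1)
        assert maps.so2[0, 0] == 1.0

    def test_direct_ratio(self):
        maps = so2_map(self._maps(0.1, 0.9), total_hb_threshold=0.1)
        assert maps.so2[0, 0] == pytest.approx(0.9)

    def test_negatives_clamped_before_ratio(self):
        maps = so2_map(self._maps(-0.2, 0.5), total_hb_threshold=0.1)
        assert maps.so2[0, 0] == 1.0

    def test_low_total_masked(self):
        maps = so2_map(self._maps(0.01, 0.01), total_hb_threshold=0.1)
        assert maps.so2.mask[0, 0]
        assert maps.threshold_used == 0.1

    def test_default_threshold_from_percentile(self):
        rng = np.random.default_rng(0)
        from trimodal.spectral import UnmixedMaps
        maps = UnmixedMaps(conc={"Hb": rng.uniform(0, 1, (50, 50)),
                                 "HbO2": rng.uniform(0, 1, (50, 50))})
        maps = so2_map(maps)
        total = maps.conc["Hb"] + maps.conc["HbO2"]
        assert maps.threshold_used == pytest.approx(
            0.05 * np.percentile(total, 99))
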