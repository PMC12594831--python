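"""Delay-and-sum reconstruction, display chain and frame sequencing."""

import numpy as np
import pytest

from trimodal.benchmarks import das_reference
from trimodal.forward import (AcquisitionSpec, ChannelData, TransducerSpec,
                              pa_channel_data, us_channel_data)
from trimodal.phantom import Background, GridSpec, make_phantom
from trimodal.pipeline import (IN_VIVO_WAVELENGTHS, simulate_frame,
                               two_tube_scene)
from trimodal.recon import (BScanImage, ImageGrid, IncompleteCycleError,
                            das_pa, das_us, envelope, envelope_log,
                            frame_sequencer)

from conftest import point_phantom


def _zero_pa_channel(tx, n_samples=256):
    return ChannelData(traces=np.zeros((1, tx.n_elements, n_samples)),
                       modality="PA",
                       events=[{"wavelength_nm": 756.0, "t0_s": 0.0}],
                       sampling_mhz=40.0, gain_db=54.0)


class TestDasPA:
    def test_zero_traces_zero_image(self, tx):
        img = das_pa(_zero_pa_channel(tx), tx)
        assert not np.any(img.pixels)

    def test_default_grid_spans_40_by_20_mm(self, tx):
        img = das_pa(_zero_pa_channel(tx), tx)
        assert img.extent_mm == (40.0, 20.0)
        assert img.pixels.shape == (200, 400)

    def test_matches_brute_force_oracle(self, quiet_acq):
        tx16 = TransducerSpec(n_elements=16)
        grid = GridSpec((48, 1, 64), 0.15)
        p = point_phantom(grid, [(-1.5, 5.0), (0.4, 6.0), (1.5, 8.0)])
        cd = pa_channel_data(p, np.ones(grid.shape), tx16, quiet_acq, 756.0)
        igrid = ImageGrid(7.2, 9.6, 0.15)
        fast = das_pa(cd, tx16, igrid).pixels
        ref = das_reference(cd, tx16, igrid)
        assert np.abs(fast - ref).max() <= 1e-9 * np.abs(ref).max()

    def test_point_source_peak_within_one_pixel(self, tx, quiet_acq):
        grid = GridSpec((64, 1, 160), 0.125)
        p = point_phantom(grid, [(0.0, 12.0)])
        ix = int(np.argmin(np.abs(grid.x_mm)))
        iz = int(np.argmin(np.abs(grid.z_mm - 12.0)))
        cd = pa_channel_data(p, np.ones(grid.shape), tx, quiet_acq, 796.0)
        igrid = ImageGrid(grid.extent_mm[0], grid.extent_mm[2], 0.125)
        env = envelope(das_pa(cd, tx, igrid)).pixels
        pz, px = np.unravel_index(np.argmax(env), env.shape)
        assert abs(igrid.x_mm[px] - grid.x_mm[ix]) <= 0.125 + 1e-9
        assert abs(igrid.z_mm[pz] - grid.z_mm[iz]) <= 0.125 + 1e-9

    def test_gain_invariance_after_normalization(self, tx):
        grid = GridSpec((48, 1, 96), 0.15)
        p = point_phantom(grid, [(0.0, 8.0)])
        igrid = ImageGrid(7.2, 14.4, 0.15)
        imgs = []
        for gain in (54.0, 0.0):
            acq = AcquisitionSpec(pa_gain_db=gain, noise_rms=0.0, seed=0)
            cd = pa_channel_data(p, np.ones(grid.shape), tx, acq, 756.0)
            imgs.append(das_pa(cd, tx, igrid).pixels)
        assert np.allclose(imgs[0], imgs[1],
                           atol=1e-9 * np.abs(imgs[1]).max())

    def test_linearity_on_channel_data(self, tx, quiet_acq):
        grid = GridSpec((48, 1, 96), 0.15)
        p = point_phantom(grid, [(0.0, 8.0)])
        cd = pa_channel_data(p, np.ones(grid.shape), tx, quiet_acq, 756.0)
        igrid = ImageGrid(7.2, 14.4, 0.15)
        one = das_pa(cd, tx, igrid).pixels
        cd.traces = 2.0 * cd.traces
        two = das_pa(cd, tx, igrid).pixels
        assert np.allclose(two, 2.0 * one)


class TestDasUS:
    @pytest.fixture()
    def scatter_channel(self, tx, quiet_acq):
        grid = GridSpec((64, 1, 120), 0.125)
        p = make_phantom([], grid, Background(scatter_density_per_mm3=0.0),
                         seed=0)
        ix = int(np.argmin(np.abs(grid.x_mm - 0.3)))
        iz = int(np.argmin(np.abs(grid.z_mm - 8.0)))
        p.scatter_amp[ix, 0, iz] = 1.0
        truth = (grid.x_mm[ix], grid.z_mm[iz])
        return us_channel_data(p, tx, quiet_acq, 0.0), truth, grid

    def test_single_scatterer_peak_within_one_pixel(self, tx, scatter_channel):
        cd, truth, grid = scatter_channel
        igrid = ImageGrid(grid.extent_mm[0], grid.extent_mm[2], 0.125)
        env = envelope(das_us([cd], tx, igrid)).pixels
        pz, px = np.unravel_index(np.argmax(env), env.shape)
        assert abs(igrid.x_mm[px] - truth[0]) <= 0.125 + 1e-9
        assert abs(igrid.z_mm[pz] - truth[1]) <= 0.125 + 1e-9

    def test_compounding_identical_packets_is_linear(self, tx,
                                                     scatter_channel):
        cd, _, grid = scatter_channel
        igrid = ImageGrid(grid.extent_mm[0], grid.extent_mm[2], 0.25)
        one = das_us([cd], tx, igrid).pixels
        three = das_us([cd, cd, cd], tx, igrid).pixels
        assert np.allclose(three, 3.0 * one)

    def test_mismatched_sampling_rates_rejected(self, tx, scatter_channel):
        cd, _, _ = scatter_channel
        other = ChannelData(traces=cd.traces.copy(), modality="US",
                            events=cd.events, sampling_mhz=50.0,
                            gain_db=cd.gain_db)
        with pytest.raises(ValueError, match="sampling"):
            das_us([cd, other], tx)

    def test_incoherent_mode_returns_envelope_kind(self, tx, scatter_channel):
        cd, _, grid = scatter_channel
        igrid = ImageGrid(grid.extent_mm[0], grid.extent_mm[2], 0.25)
        img = das_us([cd], tx, igrid, compounding="incoherent")
        assert img.kind == "env"
        assert np.all(img.pixels >= 0)


class TestEnvelopeLog:
    def test_tone_envelope_constant(self):
        z = np.arange(400)
        rf = BScanImage(np.cos(2 * np.pi * 0.175 * z)[:, None]
                        * np.ones((1, 8)), (0.8, 40.0), 0.1, "PA")
        env = envelope(rf).pixels[50:-50]
        assert env.max() / env.min() - 1 < 0.01

    def test_max_pixel_maps_to_zero_db(self):
        rng = np.random.default_rng(0)
        rf = BScanImage(rng.normal(size=(64, 32)), (3.2, 6.4), 0.1, "US")
        db = envelope_log(rf, 40.0)
        assert db.pixels.max() == pytest.approx(0.0)
        assert db.pixels.min() >= -40.0
        assert db.dynamic_range_db == 40.0

    def test_matches_independent_fft_hilbert_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(128, 16))
        rf = BScanImage(x, (1.6, 12.8), 0.1, "PA")
        env = envelope(rf).pixels
        # independent analytic-signal construction via direct FFT masking
        X = np.fft.fft(x, axis=0)
        h = np.zeros(128)
        h[0] = 1.0
        h[1:64] = 2.0
        h[64] = 1.0
        oracle = np.abs(np.fft.ifft(X * h[:, None], axis=0))
        assert np.abs(env - oracle).max() < 1e-9 * oracle.max()

    def test_all_zero_image_floors_with_warning(self, tx):
        rf = das_pa(_zero_pa_channel(tx), tx)
        with pytest.warns(UserWarning, match="all-zero"):
            db = envelope_log(rf, 30.0)
        assert np.all(db.pixels == -30.0)


@pytest.fixture(scope="module")
def stream(tx):
    scene = two_tube_scene(grid=GridSpec((64, 1, 48), 0.15), seed=0)
    acq = AcquisitionSpec(wavelengths_nm=IN_VIVO_WAVELENGTHS,
                          noise_rms=0.0, seed=0)
    return simulate_frame(scene, tx, acq)


class TestFrameSequencer:

    def test_five_wavelength_cycle_bundles(self, stream):
        bundles = list(frame_sequencer(stream))
        assert len(bundles) == 1
        assert sorted(bundles[0].pa) == sorted(IN_VIVO_WAVELENGTHS)
        assert len(bundles[0].us_packets) == 3
        angles = [p.events[0]["steer_angle_deg"] for p in bundles[0].us_packets]
        assert angles == [0.0, -10.0, 10.0]

    def test_four_wavelength_cycle(self, tx):
        scene = two_tube_scene(grid=GridSpec((64, 1, 48), 0.15), seed=0)
        acq = AcquisitionSpec(wavelengths_nm=(690.0, 720.0, 756.0, 796.0),
                              noise_rms=0.0, seed=0)
        bundles = list(frame_sequencer(simulate_frame(scene, tx, acq)))
        assert len(bundles[0].pa) == 4

    def test_empty_container_empty_iterator(self):
        assert list(frame_sequencer([])) == []

    def test_missing_wavelength_raises_naming_frame(self, stream):
        # drop one PA event, then restart the cycle
        broken = [it for it in stream
                  if not (it.modality == "PA"
                          and it.events[0]["wavelength_nm"] == 756.0)]
        broken = broken + list(stream)
        with pytest.raises(IncompleteCycleError, match="frame 0"):
            list(frame_sequencer(broken))

    def test_pa_us_delay_metadata_checked(self, stream):
        bad = list(stream)
        for it in bad:
            if it.modality == "US":
                for ev in it.events:
                    ev["t0_s"] = ev["t0_s"] + 5e-5
        with pytest.raises(ValueError, match="follow PA"):
            list(frame_sequencer(bad))
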