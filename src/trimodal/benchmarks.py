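"""Worked-example and property benchmarks of the whole chain.

Each function recomputes one quantitative check from scratch by running the
package: transducer resonance analysis, unmixing exactness, end-to-end sO2
recovery, beamformer fidelity, Monte Carlo physics, pulsation recovery,
mosaic self-consistency and diffraction-limited resolution.  Shared by the
acceptance script and the test suite.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.ndimage import gaussian_filter

from .forward import (AcquisitionSpec, BeamModel, TransducerSpec,
                      fluence_analytic, pa_channel_data)
from .mcfluence import OpticalMedium, compare_illumination, run_mc
from .metrology import (ImpedanceSpectrum, fwhm, keff_from_impedance,
                        pulsation_spectrum)
from .phantom import (Background, GridSpec, VesselSpec, blood_mix,
                      make_phantom, raised_cosine_train)
from .recon import ImageGrid, das_pa, envelope
from .spectra import SpectraTable
from .spectral import SpectralStack, build_M, fluence_compensate, so2_map, unmix
from .volume import ScanLane, stitch_mosaic
from .pipeline import BLOOD_TOTAL_MOLAR, IN_VIVO_WAVELENGTHS


def _sub_seed(seed: int, k: int) -> int:
    return int((seed * 1009 + k) % (2 ** 31 - 1))


# ---------------------------------------------------------------------------
# 1. resonance worked example

def synthesize_impedance(f_r_mhz: float = 6.53, f_a_mhz: float = 7.54,
                         loss_mhz2: float = 0.05,
                         n_points: int = 4001) -> ImpedanceSpectrum:
    """Lossy single-resonator impedance magnitude with the given extrema.

    |Z| ~ sqrt((f^2-f_r^2)^2 + a^2) / (f * sqrt((f^2-f_a^2)^2 + a^2)): a
    minimum at the series resonance and a maximum at the parallel
    (anti-)resonance, softened by a small loss term.
    """
    f = np.linspace(4.0, 10.0, n_points)
    num = np.sqrt((f ** 2 - f_r_mhz ** 2) ** 2 + loss_mhz2 ** 2)
    den = f * np.sqrt((f ** 2 - f_a_mhz ** 2) ** 2 + loss_mhz2 ** 2)
    mag = 50.0 * num / den + 1.0
    phase = np.degrees(np.arctan2(f_a_mhz ** 2 - f ** 2, loss_mhz2)
                       - np.arctan2(f_r_mhz ** 2 - f ** 2, loss_mhz2))
    return ImpedanceSpectrum(freqs_mhz=f, magnitude_ohm=mag, phase_deg=phase)


def keff_worked_example() -> dict:
    """k_eff recovered from a spectrum with extrema at 6.53 / 7.54 MHz."""
    spec = synthesize_impedance()
    f_r, f_a, keff = keff_from_impedance(spec)
    return {"value": float(keff), "n": spec.freqs_mhz.size,
            "f_r_mhz": float(f_r), "f_a_mhz": float(f_a)}


# ---------------------------------------------------------------------------
# 2. unmixing exactness

def unmixing_exactness(seed: int, n_pixels: int = 1000) -> dict:
    """Noiseless pseudo-inverse recovery of random concentration triplets."""
    spectra = SpectraTable.default()
    species = ["Hb", "HbO2", "ICG"]
    M = build_M(spectra, IN_VIVO_WAVELENGTHS, species)
    rng = np.random.default_rng(_sub_seed(seed, 2))
    C = rng.uniform(0.0, 1.0, size=(n_pixels, 3))
    PA = C @ M                                   # (pixels, k)
    stack = SpectralStack(images=PA.T.reshape(len(IN_VIVO_WAVELENGTHS),
                                              n_pixels, 1),
                          wavelengths_nm=np.array(IN_VIVO_WAVELENGTHS),
                          compensated=True)
    maps = unmix(stack, M, species=species)
    rec = np.stack([maps.conc[s].ravel() for s in species], axis=1)
    rel_err = np.abs(rec - C) / np.maximum(np.abs(C), 1e-300)
    # independent least-squares oracle
    oracle = np.linalg.lstsq(M.T, PA.T, rcond=None)[0].T
    oracle_dev = np.abs(rec - oracle).max()
    return {"value": float(rel_err.max()), "n": n_pixels,
            "oracle_max_abs_dev": float(oracle_dev)}


# ---------------------------------------------------------------------------
# 3. end-to-end sO2 recovery

def so2_recovery(seed: int, n_replicates: int = 10, so2_true: float = 0.90,
                 snr_db: float = 20.0) -> dict:
    """simulate -> reconstruct -> compensate -> unmix a synthetic artery.

    Channel noise is calibrated per wavelength set so the RMS of the active
    signal is ``snr_db`` above the noise RMS.
    """
    grid = GridSpec((96, 1, 64), 0.15)
    tube_x, tube_z, radius = 0.0, 5.0, 0.5
    vessel = VesselSpec(
        centerline=np.array([[tube_x, 0.0, tube_z], [tube_x + 1e-3, 0.0, tube_z]]),
        radius_mm=radius, species_mix=blood_mix(BLOOD_TOTAL_MOLAR, so2_true))
    tx = TransducerSpec()
    spectra = SpectraTable.default()
    wavelengths = IN_VIVO_WAVELENGTHS
    img_grid = ImageGrid(x_span_mm=grid.extent_mm[0],
                         z_span_mm=grid.extent_mm[2], pixel_size_mm=0.15)

    # calibrate noise on a noiseless mid-wavelength run
    phantom = make_phantom([vessel], grid, Background(), seed=_sub_seed(seed, 3))
    acq0 = AcquisitionSpec(wavelengths_nm=wavelengths, noise_rms=0.0, seed=0)
    phi0 = fluence_analytic(np.full(grid.shape, phantom.background.mu_a_mm),
                            phantom.mu_s_prime_background,
                            BeamModel("coaxial"), grid)
    cd0 = pa_channel_data(phantom, phi0, tx, acq0, 796.0, spectra)
    active = cd0.traces[np.abs(cd0.traces) > 0]
    signal_rms = active.std() / 10.0 ** (acq0.pa_gain_db / 20.0)
    noise_rms = signal_rms / 10.0 ** (snr_db / 20.0)

    X, Z = np.meshgrid(img_grid.x_mm, img_grid.z_mm, indexing="xy")
    roi = (X - tube_x) ** 2 + (Z - tube_z) ** 2 <= (0.7 * radius) ** 2
    # unnormalized extinction rows keep the Hb/HbO2 ratio physical for sO2
    M = build_M(spectra, wavelengths, ["Hb", "HbO2", "ICG"], normalize=False)

    means = []
    for rep in range(n_replicates):
        acq = AcquisitionSpec(wavelengths_nm=wavelengths, noise_rms=noise_rms,
                              seed=_sub_seed(seed, 100 + rep))
        rng = np.random.default_rng(acq.seed)
        images = []
        for wl in wavelengths:
            phi = fluence_analytic(np.full(grid.shape,
                                           phantom.background.mu_a_mm),
                                   phantom.mu_s_prime_background,
                                   BeamModel("coaxial"), grid)
            cd = pa_channel_data(phantom, phi, tx, acq, wl, spectra, rng=rng)
            images.append(envelope(das_pa(cd, tx, img_grid)).pixels)
        stack = SpectralStack(images=np.stack(images),
                              wavelengths_nm=np.array(wavelengths),
                              pixel_size_mm=img_grid.pixel_size_mm)
        stack = fluence_compensate(stack, object_mask=roi)
        maps = so2_map(unmix(stack, M, species=["Hb", "HbO2", "ICG"]))
        vals = maps.so2[roi]
        vals = vals.compressed() if np.ma.isMaskedArray(vals) else vals
        means.append(float(np.mean(vals)))
    means = np.array(means)
    return {"value": float(means.mean()), "n": n_replicates,
            "per_replicate": means.tolist(),
            "max_abs_error": float(np.abs(means - so2_true).max()),
            "so2_true": so2_true}


# ---------------------------------------------------------------------------
# 4. beamformer oracle

def das_reference(channel, tx, grid, apodization="hann", f_number=1.0,
                  sound_speed_mps=1540.0, event_index=0):
    """Brute-force per-pixel delay-and-sum (independent of the fast path)."""
    trace = channel.traces[event_index] * 10.0 ** (-channel.gain_db / 20.0)
    c = sound_speed_mps / 1000.0
    fs = channel.sampling_mhz
    n = trace.shape[1]
    out = np.zeros((grid.nz, grid.nx))
    elem_x = tx.element_x_mm()
    for iz, z in enumerate(grid.z_mm):
        for ix, x in enumerate(grid.x_mm):
            acc = 0.0
            for e, xe in enumerate(elem_x):
                d = abs(x - xe)
                half = max(z / (2.0 * f_number), 1e-9)
                if d > half:
                    continue
                if apodization == "hann":
                    w = 0.5 * (1.0 + math.cos(math.pi * d / half))
                else:
                    w = 1.0
                pos = math.sqrt((x - xe) ** 2 + z ** 2) / c * fs
                i0 = math.floor(pos)
                if i0 < 0 or i0 >= n - 1:
                    continue
                frac = pos - i0
                acc += w * (trace[e, i0] * (1.0 - frac)
                            + trace[e, i0 + 1] * frac)
            out[iz, ix] = acc
    return out


def beamformer_oracle(seed: int) -> dict:
    """16-element toy with 3 point sources vs the brute-force delay-sum."""
    tx = TransducerSpec(n_elements=16)
    grid = GridSpec((64, 1, 64), 0.15)
    sources = [(-2.0, 5.0), (0.1, 6.5), (2.0, 8.0)]  # (x, z) mm
    dv = grid.voxel_size_mm
    conc = np.zeros(grid.shape)
    truth = []
    for sx, sz in sources:
        i = int(np.argmin(np.abs(grid.x_mm - sx)))
        k = int(np.argmin(np.abs(grid.z_mm - sz)))
        conc[i, 0, k] = 1e-5
        truth.append((grid.x_mm[i], grid.z_mm[k]))
    phantom = make_phantom([], grid, Background(), seed=_sub_seed(seed, 4))
    phantom.conc["ICG"] = conc
    acq = AcquisitionSpec(noise_rms=0.0, seed=_sub_seed(seed, 4))
    cd = pa_channel_data(phantom, np.ones(grid.shape), tx, acq, 796.0)
    img_grid = ImageGrid(x_span_mm=grid.extent_mm[0],
                         z_span_mm=grid.extent_mm[2], pixel_size_mm=dv)
    img = das_pa(cd, tx, img_grid)
    ref = das_reference(cd, tx, img_grid)
    scale = np.abs(ref).max()
    rel = np.abs(img.pixels - ref).max() / scale

    env = envelope(img).pixels
    max_off = 0
    for (txx, tzz) in truth:
        ix = int(np.argmin(np.abs(img_grid.x_mm - txx)))
        iz = int(np.argmin(np.abs(img_grid.z_mm - tzz)))
        win = env[max(iz - 6, 0):iz + 7, max(ix - 6, 0):ix + 7]
        pz, px = np.unravel_index(np.argmax(win), win.shape)
        off = max(abs(pz - min(iz, 6)), abs(px - min(ix, 6)))
        max_off = max(max_off, off)
    return {"value": float(rel), "n": int(img.pixels.size),
            "peak_offset_px": int(max_off)}


# ---------------------------------------------------------------------------
# 5. Monte Carlo physics

def mc_beer_lambert(seed: int, n_photons: int = 100_000,
                    mua_cm: float = 2.0) -> dict:
    """Absorption-only pencil beam vs the Beer-Lambert closed form.

    Per depth voxel the expected absorbed weight is
    N (exp(-mua z_k) - exp(-mua z_{k+1})); the observed deposit is compared
    in units of the binomial standard error.
    """
    medium = OpticalMedium(shape=(41, 41, 30), voxel_cm=0.05, mua=mua_cm,
                           mus=0.0, g=0.0)
    pencil = BeamModel("coaxial", fiber_diameter_mm=0.0,
                       divergence_full_angle_deg=0.0)
    fv = run_mc(medium, pencil, n_photons, _sub_seed(seed, 5))
    dv = medium.voxel_cm
    k = np.arange(medium.shape[2])
    p = np.exp(-mua_cm * k * dv) - np.exp(-mua_cm * (k + 1) * dv)
    expected = n_photons * p
    observed = fv.fluence[20, 20, :] * mua_cm * dv ** 3 * n_photons
    se = np.sqrt(n_photons * p * (1.0 - p))
    z_scores = np.abs(observed - expected) / se
    return {"value": float(z_scores.max()), "n": n_photons,
            "energy_balance_rel_err": float(fv.energy_balance_error),
            "absorbed_fraction": float(fv.absorbed_fraction)}


def mc_illumination_comparison(seed: int, n_photons: int = 100_000) -> dict:
    """Coaxial vs oblique on-axis fluence in homogeneous soft tissue."""
    medium = OpticalMedium(shape=(60, 60, 30), voxel_cm=0.05,
                           mua=0.2, mus=100.0, g=0.9)
    report = compare_illumination(medium, BeamModel("coaxial"),
                                  BeamModel("oblique"), n_photons,
                                  _sub_seed(seed, 6))
    z = report["z_cm"]
    deep = z >= 0.1  # depths beyond 1 mm
    frac = float(np.mean(report["phi_coaxial"][deep]
                         >= report["phi_oblique"][deep]))
    return {"value": frac, "n": n_photons,
            "median_ratio": float(np.median(report["ratio"][deep]))}


# ---------------------------------------------------------------------------
# 6. pulsation recovery

def pulsation_recovery(seed: int, heart_rate_bpm: float = 84.0,
                       n_frames: int = 200, frame_rate_hz: float = 20.0,
                       noise_frac: float = 0.10) -> dict:
    """Fundamental/harmonic detection on a noisy raised-cosine pulse train."""
    rng = np.random.default_rng(_sub_seed(seed, 7))
    f0 = heart_rate_bpm / 60.0
    t = np.arange(n_frames) / frame_rate_hz
    signal = raised_cosine_train(f0 * t)
    series = 1.0 + 0.2 * signal + noise_frac * 0.2 * rng.normal(size=n_frames)
    result = pulsation_spectrum(series, frame_rate_hz,
                                expected_fundamental_hz=f0)
    return {"value": float(result["fundamental_hz"]), "n": n_frames,
            "n_harmonics": len(result["harmonics_hz"]),
            "true_hz": f0}


# ---------------------------------------------------------------------------
# 7. mosaic self-consistency

def mosaic_consistency(seed: int) -> dict:
    """Two lanes cut from one volume must re-stitch to the original."""
    rng = np.random.default_rng(_sub_seed(seed, 8))
    nz, ny, nx = 40, 6, 120
    px = 0.1
    truth = gaussian_filter(rng.normal(size=(nz, ny, nx)), 2.0)
    cut = 70, 50  # lane A columns [0:70], lane B [50:120] -> 2 mm overlap
    lane_a = ScanLane(np.transpose(truth[:, :, :cut[0]], (1, 0, 2)), px,
                      y_step_mm=0.5,
                      lane_x_offset_mm=cut[0] * px / 2)
    lane_b = ScanLane(np.transpose(truth[:, :, cut[1]:], (1, 0, 2)), px,
                      y_step_mm=0.5,
                      lane_x_offset_mm=cut[1] * px + (nx - cut[1]) * px / 2)
    vol = stitch_mosaic([lane_a, lane_b])
    err = np.abs(vol.voxels - truth).max()

    ones_a = ScanLane(np.ones_like(lane_a.slices), px, y_step_mm=0.5,
                      lane_x_offset_mm=lane_a.lane_x_offset_mm)
    ones_b = ScanLane(np.ones_like(lane_b.slices), px, y_step_mm=0.5,
                      lane_x_offset_mm=lane_b.lane_x_offset_mm)
    wdev = np.abs(stitch_mosaic([ones_a, ones_b]).voxels - 1.0).max()
    return {"value": float(err), "n": int(truth.size),
            "feather_weight_max_dev": float(wdev)}


# ---------------------------------------------------------------------------
# 8. resolution sanity

def resolution_sanity(seed: int) -> dict:
    """Point-target lateral FWHM at the 20 mm focus vs lambda*F#.

    Uniform (boxcar) receive apodization with spreading-weight back
    projection over the full aperture, matching the uniform-aperture
    assumption of the diffraction estimate; the image grid is aligned so
    the source sits on a pixel center.
    """
    tx = TransducerSpec()
    grid = GridSpec((64, 1, 256), 0.1)
    conc = np.zeros(grid.shape)
    ix = int(np.argmin(np.abs(grid.x_mm - 0.0)))
    iz = int(np.argmin(np.abs(grid.z_mm - 20.0)))
    conc[ix, 0, iz] = 1e-5
    phantom = make_phantom([], grid, Background(), seed=_sub_seed(seed, 9))
    phantom.conc["ICG"] = conc
    acq = AcquisitionSpec(noise_rms=0.0, seed=_sub_seed(seed, 9))
    cd = pa_channel_data(phantom, np.ones(grid.shape), tx, acq, 796.0)
    # 6.35 mm span puts the source voxel center on an image pixel center
    img_grid = ImageGrid(x_span_mm=6.35, z_span_mm=25.6, pixel_size_mm=0.05)
    env = envelope(das_pa(cd, tx, img_grid, apodization="boxcar",
                          spreading_weight=True)).pixels
    pz, _ = np.unravel_index(np.argmax(env), env.shape)
    measured = fwhm(env[pz, :], img_grid.pixel_size_mm)
    wavelength_mm = 1.540 / tx.center_freq_mhz
    predicted = wavelength_mm * float(img_grid.z_mm[pz]) / tx.aperture_mm
    return {"value": float(measured / predicted), "n": tx.n_elements,
            "fwhm_mm": float(measured), "diffraction_mm": float(predicted)}


# ---------------------------------------------------------------------------

def run_all(seed: int) -> dict:
    """Every benchmark, keyed by short descriptive names."""
    keff = keff_worked_example()
    um = unmixing_exactness(seed)
    so2 = so2_recovery(seed)
    das = beamformer_oracle(seed)
    bl = mc_beer_lambert(seed)
    ill = mc_illumination_comparison(seed)
    puls = pulsation_recovery(seed)
    mosaic = mosaic_consistency(seed)
    res = resolution_sanity(seed)
    return {
        "keff": {"value": round(keff["value"], 4), "n": keff["n"]},
        "unmix_max_rel_err": {"value": um["value"], "n": um["n"]},
        "so2_recovered": {"value": so2["value"], "n": so2["n"]},
        "das_oracle_max_rel_err": {"value": das["value"], "n": das["n"]},
        "das_peak_offset_px": {"value": das["peak_offset_px"], "n": das["n"]},
        "mc_beer_lambert_max_z": {"value": bl["value"], "n": bl["n"]},
        "mc_energy_balance_rel_err": {"value": bl["energy_balance_rel_err"],
                                      "n": bl["n"]},
        "mc_coaxial_dominance": {"value": ill["value"], "n": ill["n"]},
        "pulsation_fundamental_hz": {"value": puls["value"], "n": puls["n"]},
        "pulsation_n_harmonics": {"value": puls["n_harmonics"],
                                  "n": puls["n"]},
        "mosaic_max_abs_err": {"value": mosaic["value"], "n": mosaic["n"]},
        "feather_weight_max_dev": {"value": mosaic["feather_weight_max_dev"],
                                   "n": mosaic["n"]},
        "lateral_fwhm_over_diffraction": {"value": res["value"],
                                          "n": res["n"]},
    }
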