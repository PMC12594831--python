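"""Transducer and image-quality metrology.

Resonance analysis of impedance spectra (k_eff), pulse-echo spectral
summaries, inter-element crosstalk, FWHM resolution estimation, contrast-to-
noise ratio, pulsation spectral analysis and contrast-agent fold change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, get_window


class DetectionError(RuntimeError):
    """A required spectral/temporal feature could not be located."""


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Electrical impedance magnitude/phase vs frequency."""

    freqs_mhz: np.ndarray
    magnitude_ohm: np.ndarray
    phase_deg: np.ndarray | None = None

    def __post_init__(self):
        f = np.asarray(self.freqs_mhz, dtype=float)
        m = np.asarray(self.magnitude_ohm, dtype=float)
        if f.size != m.size:
            raise ValueError("freqs and magnitude must have equal length")
        if f.size < 32:
            raise ValueError("need >= 32 points spanning the resonance region")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be ascending")
        if np.any(m <= 0):
            raise ValueError("impedance magnitude must be positive")
        object.__setattr__(self, "freqs_mhz", f)
        object.__setattr__(self, "magnitude_ohm", m)


@dataclass(frozen=True)
class PulseEcho:
    """Pulse-echo impulse-response waveform of one element."""

    waveform: np.ndarray
    sampling_mhz: float
    element_index: int = 0

    def __post_init__(self):
        w = np.asarray(self.waveform, dtype=float)
        if not np.all(np.isfinite(w)):
            raise ValueError("waveform must be finite")
        object.__setattr__(self, "waveform", w)


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-sample extremum location by parabola through (i-1, i, i+1)."""
    if i == 0 or i == len(y) - 1:
        return float(x[i]), float(y[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return float(x[i]), float(y[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    dx = x[1] - x[0]
    return float(x[i] + delta * dx), float(y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta)


def keff_from_frequencies(f_r_mhz: float, f_a_mhz: float) -> float:
    """Effective electromechanical coupling: sqrt(1 - (f_r/f_a)^2)."""
    if f_a_mhz <= 0 or f_r_mhz < 0 or f_r_mhz > f_a_mhz:
        raise ValueError("need 0 <= f_r <= f_a")
    return math.sqrt(1.0 - (f_r_mhz / f_a_mhz) ** 2)


def keff_from_impedance(spec: ImpedanceSpectrum) -> tuple[float, float, float]:
    """Locate resonance/anti-resonance and derive k_eff.

    f_r is the impedance-magnitude minimum, f_a the subsequent maximum, both
    refined to sub-sample precision with a parabolic fit; k_eff follows the
    standard resonance relation sqrt(1 - (f_r/f_a)^2).
    """
    mag = spec.magnitude_ohm
    f = spec.freqs_mhz
    i_min = int(np.argmin(mag))
    if i_min >= len(mag) - 2:
        raise DetectionError("no anti-resonance maximum after the minimum")
    i_max = i_min + 1 + int(np.argmax(mag[i_min + 1:]))
    if mag[i_max] <= mag[i_min]:
        raise DetectionError("no clear resonance/anti-resonance extremum pair")
    f_r, _ = _parabolic_refine(f, mag, i_min)
    f_a, _ = _parabolic_refine(f, mag, i_max)
    return f_r, f_a, keff_from_frequencies(f_r, f_a)


def pulse_echo_metrics(pe: PulseEcho,
                       echo_threshold: float = 0.2) -> tuple[float, float, float]:
    """Center frequency, -6 dB fractional bandwidth and SNR of a pulse echo.

    Amplitude spectrum via Hann-windowed FFT; f_low/f_high are the -6 dB
    crossings around the peak, center = (f_low + f_high)/2, fractional
    bandwidth = (f_high - f_low)/center.  SNR is the peak signal amplitude
    over the RMS of the pre-echo noise window (samples before the waveform
    first exceeds ``echo_threshold`` of its peak).
    """
    x = pe.waveform
    n = x.size
    peak = np.abs(x).max()
    if peak <= 0:
        raise DetectionError("no dominant echo in the waveform")
    spec = np.abs(np.fft.rfft(x * get_window("hann", n)))
    freqs = np.fft.rfftfreq(n, d=1.0 / pe.sampling_mhz)
    ip = int(np.argmax(spec))
    half = spec[ip] * 10.0 ** (-6.0 / 20.0)
    lo = np.where(spec[:ip] < half)[0]
    hi = np.where(spec[ip:] < half)[0]
    if lo.size == 0 or hi.size == 0:
        raise DetectionError(
            "no -6 dB crossings: bandwidth undefined "
            "(spectral-resolution floor for a pure tone)")
    i_lo = lo[-1]
    f_low = np.interp(half, spec[i_lo:i_lo + 2], freqs[i_lo:i_lo + 2])
    i_hi = ip + hi[0]
    f_high = np.interp(half, spec[i_hi - 1:i_hi + 1][::-1],
                       freqs[i_hi - 1:i_hi + 1][::-1])
    center = 0.5 * (f_low + f_high)
    frac_bw = (f_high - f_low) / center

    first = int(np.argmax(np.abs(x) >= echo_threshold * peak))
    guard = max(first - int(pe.sampling_mhz), 0)  # 1 us guard before the echo
    noise = x[:guard]
    if noise.size < 8:
        snr_db = float("inf")
    else:
        rms = np.sqrt(np.mean(noise ** 2))
        snr_db = float("inf") if rms == 0 else 20.0 * math.log10(peak / rms)
    return float(center), float(frac_bw), float(snr_db)


def _band_rms(x: np.ndarray, fs_mhz: float, band_mhz: tuple[float, float]) -> float:
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs_mhz)
    mask = (freqs >= band_mhz[0]) & (freqs <= band_mhz[1])
    spec = np.where(mask, spec, 0.0)
    return float(np.sqrt(np.mean(np.fft.irfft(spec, n=x.size) ** 2)))


def crosstalk_db(drive: np.ndarray, neighbors, fs_mhz: float,
                 band_mhz: tuple[float, float] = (1.0, 9.0),
                 threshold_db: float = -30.0) -> dict:
    """Band-limited RMS coupling of each neighbor relative to the driven element.

    Evaluated over 1-9 MHz by default; the report flags each neighbor order
    against the -30 dB acceptance threshold.
    """
    if band_mhz[1] > fs_mhz / 2:
        raise ValueError("band must lie within Nyquist")
    drive = np.asarray(drive, dtype=float)
    d_rms = _band_rms(drive, fs_mhz, band_mhz)
    if d_rms == 0:
        raise ValueError("zero drive RMS")
    out = {"band_mhz": band_mhz, "threshold_db": threshold_db, "orders": []}
    for order, nb in enumerate(neighbors, start=1):
        n_rms = _band_rms(np.asarray(nb, dtype=float), fs_mhz, band_mhz)
        db = -math.inf if n_rms == 0 else 20.0 * math.log10(n_rms / d_rms)
        out["orders"].append({"order": order, "crosstalk_db": db,
                              "passes": db <= threshold_db})
    return out


def fwhm(profile: np.ndarray, spacing_mm: float) -> float:
    """Full width at half maximum by linear-interpolated crossings (mm)."""
    y = np.asarray(profile, dtype=float)
    if y.size < 3:
        raise ValueError("profile too short")
    ip = int(np.argmax(y))
    if ip == 0 or ip == y.size - 1:
        raise DetectionError("peak at profile boundary: FWHM undefined")
    half = y[ip] / 2.0
    left = np.where(y[:ip] <= half)[0]
    right = np.where(y[ip:] <= half)[0]
    if left.size == 0 or right.size == 0:
        raise DetectionError("half-maximum crossing outside profile")
    i = left[-1]
    xl = i + (half - y[i]) / (y[i + 1] - y[i])
    j = ip + right[0]
    xr = j - 1 + (half - y[j - 1]) / (y[j] - y[j - 1])
    return float((xr - xl) * spacing_mm)


def cnr(image: np.ndarray, roi_target: np.ndarray, roi_background: np.ndarray,
        denominator: str = "pooled") -> float:
    """Contrast-to-noise ratio between two ROIs on linear-envelope pixels.

    Default |mu_t - mu_b| / sqrt(sigma_t^2 + sigma_b^2); the alternative
    ``denominator='background'`` uses |mu_t - mu_b| / sigma_b.
    """
    img = np.asarray(image, dtype=float)
    roi_t = np.asarray(roi_target, dtype=bool)
    roi_b = np.asarray(roi_background, dtype=bool)
    if np.any(roi_t & roi_b):
        raise ValueError("ROIs must be disjoint")
    if roi_t.sum() < 25 or roi_b.sum() < 25:
        raise ValueError("each ROI needs >= 25 pixels")
    t = img[roi_t]
    b = img[roi_b]
    if denominator == "pooled":
        denom = math.sqrt(t.var() + b.var())
    elif denominator == "background":
        denom = b.std()
    else:
        raise ValueError("denominator must be 'pooled' or 'background'")
    if denom == 0:
        raise ValueError("zero pooled variance")
    return float(abs(t.mean() - b.mean()) / denom)


def pulsation_spectrum(series: np.ndarray, frame_rate_hz: float,
                       expected_fundamental_hz: float | None = None) -> dict:
    """Fundamental frequency and harmonics of an ROI intensity time series.

    Linear detrend, Hann window, FFT; the fundamental is the largest non-DC
    peak, harmonics are spectral peaks near integer multiples within the
    frequency resolution.  A constant series yields a flagged no-peak result.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 64:
        raise ValueError("need >= 64 frames")
    if expected_fundamental_hz is not None and \
            frame_rate_hz <= 2 * expected_fundamental_hz:
        raise ValueError("frame rate must exceed twice the fundamental")
    t = np.arange(n)
    x = x - np.polyval(np.polyfit(t, x, 1), t)
    spec = np.abs(np.fft.rfft(x * get_window("hann", n)))
    freqs = np.fft.rfftfreq(n, d=1.0 / frame_rate_hz)
    df = freqs[1] - freqs[0]
    scale = np.abs(np.asarray(series, dtype=float)).max()
    if spec[1:].max() <= 1e-9 * max(scale, 1e-300) * n:
        return {"fundamental_hz": None, "harmonics_hz": [],
                "freqs_hz": freqs, "spectrum": spec, "no_peak": True}
    i0 = 1 + int(np.argmax(spec[1:]))
    f0, _ = _parabolic_refine(freqs, spec, i0)
    peaks, _ = find_peaks(spec)
    harmonics = []
    for m in range(2, int(freqs[-1] / f0) + 1):
        target = m * f0
        near = peaks[np.abs(freqs[peaks] - target) <= 1.5 * df]
        if near.size:
            best = near[np.argmax(spec[near])]
            harmonics.append(float(freqs[best]))
    return {"fundamental_hz": float(f0), "harmonics_hz": harmonics,
            "freqs_hz": freqs, "spectrum": spec, "no_peak": False}


def fold_change(pre_roi_mean: float, post_roi_mean: float) -> float:
    """Post/pre ROI mean ratio (e.g. ICG enhancement after injection)."""
    if pre_roi_mean <= 0:
        raise ValueError("pre-injection ROI mean must be positive")
    return float(post_roi_mean) / float(pre_roi_mean)
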