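"""Time-delay beamforming and B-mode display chain.

Delay-and-sum (DAS) reconstruction of PA (one-way delays) and steered
line-beam US (two-way delays) channel data onto a pixel grid, followed by
analytic-signal envelope detection and log compression.  The default output
grid spans the 40 x 20 mm field of view at 0.1 mm pixels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy.signal import hilbert

from .forward import ChannelData, TransducerSpec


class IncompleteCycleError(RuntimeError):
    """A spectral cycle is missing one or more wavelengths."""


@dataclass(frozen=True)
class ImageGrid:
    """Beamforming pixel grid: [z, x] pixels, mm coordinates."""

    x_span_mm: float = 40.0
    z_span_mm: float = 20.0
    pixel_size_mm: float = 0.1
    z0_mm: float = 0.0

    @property
    def nx(self) -> int:
        return int(round(self.x_span_mm / self.pixel_size_mm))

    @property
    def nz(self) -> int:
        return int(round(self.z_span_mm / self.pixel_size_mm))

    @property
    def x_mm(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.pixel_size_mm - self.x_span_mm / 2

    @property
    def z_mm(self) -> np.ndarray:
        return self.z0_mm + (np.arange(self.nz) + 0.5) * self.pixel_size_mm


@dataclass
class BScanImage:
    """Cross-sectional B-mode image, pixels indexed [z, x]."""

    pixels: np.ndarray
    extent_mm: tuple[float, float]          # (x span, z span)
    pixel_size_mm: float
    modality: str
    kind: str = "rf"                        # rf | env | db
    wavelength_nm: float | None = None
    frame_index: int | None = None
    dynamic_range_db: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        nz, nx = self.pixels.shape
        ex, ez = self.extent_mm
        if abs(nx * self.pixel_size_mm - ex) > 1e-6 or \
           abs(nz * self.pixel_size_mm - ez) > 1e-6:
            raise ValueError("extent inconsistent with pixel counts")
        if self.kind == "db" and self.dynamic_range_db is None:
            raise ValueError("dB images must carry their dynamic-range floor")

    @property
    def grid(self) -> ImageGrid:
        return ImageGrid(self.extent_mm[0], self.extent_mm[1], self.pixel_size_mm)


def _interp_trace(trace: np.ndarray, sample_pos: np.ndarray) -> np.ndarray:
    """Linear interpolation of one RF trace; out-of-range samples -> 0."""
    n = trace.shape[0]
    i0 = np.floor(sample_pos).astype(np.int64)
    frac = sample_pos - i0
    valid = (i0 >= 0) & (i0 < n - 1)
    i0c = np.clip(i0, 0, n - 2)
    out = trace[i0c] * (1.0 - frac) + trace[i0c + 1] * frac
    out[~valid] = 0.0
    return out


def _aperture_weights(dist_mm: np.ndarray, z_mm: np.ndarray, f_number: float,
                      apodization: str) -> np.ndarray:
    """Dynamic-aperture receive weights: half-width z/(2 F#)."""
    half = np.maximum(z_mm / (2.0 * f_number), 1e-9)
    inside = dist_mm <= half
    if apodization == "hann":
        w = 0.5 * (1.0 + np.cos(np.pi * dist_mm / half))
    elif apodization == "boxcar":
        w = np.ones_like(dist_mm)
    else:
        raise ValueError(f"unknown apodization {apodization!r}")
    return np.where(inside, w, 0.0)


def das_pa(channel: ChannelData, tx: TransducerSpec,
           grid: ImageGrid | None = None, event_index: int = 0,
           apodization: str = "hann", f_number: float = 1.0,
           spreading_weight: bool = False,
           sound_speed_mps: float = 1540.0) -> BScanImage:
    """Delay-and-sum PA reconstruction (RF, pre-envelope).

    pixel(x, z) = sum_e w_e(x, z) * trace_e(t = dist(e, pixel)/c), linear
    interpolation between samples, Hann apodization over a dynamic receive
    aperture (F-number 1 by default), one-way delays.  Receive gain is
    normalized away via 10^(-gain_db/20).  ``spreading_weight`` multiplies
    each contribution by r/z to undo the spherical-spreading taper across
    the aperture (uniform-aperture back projection).  Pixels whose delay
    falls beyond the trace are set to 0 and flagged in provenance.
    """
    if channel.modality != "PA":
        raise ValueError("das_pa requires PA channel data")
    grid = grid or ImageGrid()
    trace = channel.traces[event_index] * 10.0 ** (-channel.gain_db / 20.0)
    c = sound_speed_mps / 1000.0
    fs = channel.sampling_mhz
    X, Z = np.meshgrid(grid.x_mm, grid.z_mm, indexing="xy")  # [z, x]
    out = np.zeros((grid.nz, grid.nx))
    clipped = False
    max_sample = (channel.n_samples - 1)
    for e, xe in enumerate(tx.element_x_mm()):
        dist = np.abs(X - xe)
        r = np.sqrt((X - xe) ** 2 + Z ** 2)
        pos = r / c * fs - channel.t0_s * 1e6 * fs
        if np.any(pos > max_sample):
            clipped = True
        w = _aperture_weights(dist, Z, f_number, apodization)
        if spreading_weight:
            w = w * r / np.maximum(Z, 1e-9)
        out += w * _interp_trace(trace[e], pos)
    ev = channel.events[event_index]
    prov = {"beamformer": "das_pa", "apodization": apodization,
            "f_number": f_number, "spreading_weight": spreading_weight,
            "clipped_pixels": clipped,
            "gain_db_normalized": channel.gain_db}
    return BScanImage(pixels=out, extent_mm=(grid.x_span_mm, grid.z_span_mm),
                      pixel_size_mm=grid.pixel_size_mm, modality="PA",
                      wavelength_nm=ev.get("wavelength_nm"), provenance=prov)


def das_us(packets: Sequence[ChannelData], tx: TransducerSpec,
           grid: ImageGrid | None = None, compounding: str = "coherent",
           apodization: str = "hann", f_number: float = 1.0,
           beam_sigma_mm: float | None = None, line_cutoff_sigma: float = 2.5,
           sound_speed_mps: float = 1540.0) -> BScanImage:
    """Two-way DAS of steered line-beam packets, then angle compounding.

    Each transmitted line is beamformed with delay (r_line + r_elem)/c over
    pixels laterally close to the steered line axis; per-packet images are
    compounded coherently (RF sum, default) or incoherently (envelope sum).
    """
    if not packets:
        raise ValueError("no packets given")
    fs = packets[0].sampling_mhz
    for p in packets:
        if p.modality != "US":
            raise ValueError("das_us requires US packets")
        if p.sampling_mhz != fs:
            raise ValueError("mismatched sampling rates across packets")
    grid = grid or ImageGrid()
    c = sound_speed_mps / 1000.0
    X, Z = np.meshgrid(grid.x_mm, grid.z_mm, indexing="xy")
    elem_x = tx.element_x_mm()
    images = []
    for p in packets:
        sig = beam_sigma_mm or p.provenance.get("beam_sigma_mm", 0.4)
        gain = 10.0 ** (-p.gain_db / 20.0)
        angle = p.events[0]["steer_angle_deg"]
        th = math.radians(angle)
        img = np.zeros((grid.nz, grid.nx))
        rx_cache = [np.sqrt((X - xe) ** 2 + Z ** 2) for xe in elem_x]
        ap_cache = [_aperture_weights(np.abs(X - xe), Z, f_number, apodization)
                    for xe in elem_x]
        for l_idx, ev in enumerate(p.events):
            xl = ev["line_x_mm"]
            dxl = X - xl
            d_perp = dxl * math.cos(th) - Z * math.sin(th)
            line_w = np.exp(-0.5 * (d_perp / sig) ** 2)
            mask = np.abs(d_perp) <= line_cutoff_sigma * sig
            if not mask.any():
                continue
            r_tx = np.sqrt(dxl ** 2 + Z ** 2)
            acc = np.zeros_like(img)
            for e in range(tx.n_elements):
                pos = (r_tx + rx_cache[e]) / c * fs
                acc += ap_cache[e] * _interp_trace(p.traces[l_idx, e] * gain,
                                                   pos)
            img += np.where(mask, line_w * acc, 0.0)
        images.append(img)

    if compounding == "coherent":
        out = np.sum(images, axis=0)
        kind = "rf"
    elif compounding == "incoherent":
        out = np.sum([np.abs(hilbert(im, axis=0)) for im in images], axis=0)
        kind = "env"
    else:
        raise ValueError("compounding must be 'coherent' or 'incoherent'")
    prov = {"beamformer": "das_us", "compounding": compounding,
            "angles_deg": [p.events[0]["steer_angle_deg"] for p in packets],
            "apodization": apodization, "f_number": f_number}
    return BScanImage(pixels=out, extent_mm=(grid.x_span_mm, grid.z_span_mm),
                      pixel_size_mm=grid.pixel_size_mm, modality="US",
                      kind=kind, provenance=prov)


def envelope(rf: BScanImage) -> BScanImage:
    """Analytic-signal magnitude along depth (linear amplitude)."""
    if rf.kind != "rf":
        raise ValueError("envelope expects an RF image")
    env = np.abs(hilbert(rf.pixels, axis=0))
    out = BScanImage(pixels=env, extent_mm=rf.extent_mm,
                     pixel_size_mm=rf.pixel_size_mm, modality=rf.modality,
                     kind="env", wavelength_nm=rf.wavelength_nm,
                     frame_index=rf.frame_index,
                     provenance=dict(rf.provenance))
    return out


def envelope_log(rf: BScanImage, dynamic_range_db: float = 40.0) -> BScanImage:
    """B-mode display: envelope, normalize to 0 dB peak, floor at -DR dB."""
    env = envelope(rf) if rf.kind == "rf" else rf
    m = env.pixels.max()
    if m <= 0:
        warnings.warn("all-zero image: maximum undefined, returning floor")
        db = np.full_like(env.pixels, -dynamic_range_db)
    else:
        with np.errstate(divide="ignore"):
            db = 20.0 * np.log10(env.pixels / m)
        db = np.maximum(db, -dynamic_range_db)
    return BScanImage(pixels=db, extent_mm=rf.extent_mm,
                      pixel_size_mm=rf.pixel_size_mm, modality=rf.modality,
                      kind="db", wavelength_nm=rf.wavelength_nm,
                      frame_index=rf.frame_index,
                      dynamic_range_db=dynamic_range_db,
                      provenance=dict(rf.provenance))


@dataclass
class FrameBundle:
    """One spectral cycle: PA channel data per wavelength + US packets."""

    frame_index: int
    pa: dict[float, ChannelData]
    us_packets: list[ChannelData]
    fl_frame: np.ndarray | None = None


def frame_sequencer(items: Sequence[ChannelData],
                    wavelengths_nm: Sequence[float] | None = None,
                    pa_us_delay_us: float | None = None) -> Iterator[FrameBundle]:
    """Group an ordered acquisition stream into spectral-cycle frame bundles.

    Expects the acquisition order of the imaging sequence: for each
    wavelength of the cycle a PA event followed by its US packets; a bundle
    is emitted once every wavelength of the cycle has been seen.  When event
    start times are present, asserts that US follows PA by the programmed
    PA->US delay.  Raises IncompleteCycleError naming the frame if a cycle
    ends with missing wavelengths.
    """
    items = list(items)
    if not items:
        return
    if wavelengths_nm is None:
        first_pa = next((it for it in items if it.modality == "PA"), None)
        if first_pa is None:
            raise ValueError("stream contains no PA events")
        wavelengths_nm = first_pa.provenance["acquisition"]["wavelengths_nm"]
    wavelengths_nm = [float(w) for w in wavelengths_nm]
    if pa_us_delay_us is None:
        first_pa = next((it for it in items if it.modality == "PA"), None)
        if first_pa is not None:
            pa_us_delay_us = first_pa.provenance.get(
                "acquisition", {}).get("pa_us_delay_us")

    frame = 0
    pa: dict[float, ChannelData] = {}
    us: list[ChannelData] = []
    last_pa_t0 = None
    for it in items:
        if it.modality == "PA":
            w = float(it.events[0]["wavelength_nm"])
            if all(x in pa for x in wavelengths_nm) and us:
                # previous cycle complete; this PA starts the next one
                yield FrameBundle(frame_index=frame, pa=dict(pa),
                                  us_packets=list(us))
                frame += 1
                pa.clear()
                us.clear()
            if w in pa:  # cycle restarted before completing
                missing = [x for x in wavelengths_nm if x not in pa]
                raise IncompleteCycleError(
                    f"frame {frame}: missing wavelengths {missing}")
            pa[w] = it
            last_pa_t0 = it.events[0].get("t0_s", 0.0)
        elif it.modality == "US":
            if pa_us_delay_us is not None and last_pa_t0 is not None:
                t0 = it.events[0].get("t0_s", 0.0)
                if t0 and abs((t0 - last_pa_t0) * 1e6 - pa_us_delay_us) > 1e-6:
                    raise ValueError(
                        f"frame {frame}: US event does not follow PA by "
                        f"{pa_us_delay_us} us")
            us.append(it)
    if pa:
        missing = [x for x in wavelengths_nm if x not in pa]
        if missing:
            raise IncompleteCycleError(
                f"frame {frame}: missing wavelengths {missing}")
        yield FrameBundle(frame_index=frame, pa=dict(pa), us_packets=list(us))
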