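"""Forward models: raw channel data and en-face fluorescence frames.

Simulates what the 64-element linear array receives.  Photoacoustics: every
absorbing voxel is an acoustic point source with initial pressure
p0 = Gamma * mu_a * Phi (Gamma fixed to 1, relative units) radiating a
band-limited pulse with 1/r spreading.  Ultrasound: line-beam transmissions
(64 lines per packet, three steered packets per frame) scattering off the
speckle grid with two-way 1/r spreading.  The elevational dimension is
collapsed per scan slice (2.5-D): channel data are generated for one
elevational slice at a time, matching a stepped B-scan acquisition.

Receive gains are bookkeeping multipliers 10^(dB/20) applied at simulation
and recorded in metadata, so reconstruction must normalize them away,
mirroring the real receive chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .phantom import DigitalPhantom, GridSpec, chromophore_mua
from .spectra import SpectraTable

DIRECTIVITY_HALF_ANGLE_DEG = 45.0  # hard element acceptance angle


@dataclass(frozen=True)
class TransducerSpec:
    """Linear-array geometry and spectral response."""

    n_elements: int = 64
    pitch_mm: float = 0.3
    center_freq_mhz: float = 7.0
    frac_bandwidth: float = 0.45
    elevational_focus_mm: float | None = None

    def __post_init__(self):
        if self.n_elements < 2:
            raise ValueError("n_elements must be >= 2")
        if not 0.0 < self.frac_bandwidth < 2.0:
            raise ValueError("frac_bandwidth must be in (0, 2)")

    @property
    def aperture_mm(self) -> float:
        return self.n_elements * self.pitch_mm

    def element_x_mm(self) -> np.ndarray:
        n = self.n_elements
        return (np.arange(n) - (n - 1) / 2.0) * self.pitch_mm

    @property
    def pulse_sigma_us(self) -> float:
        """Gaussian envelope sigma giving the -6 dB fractional bandwidth."""
        bw_mhz = self.frac_bandwidth * self.center_freq_mhz
        return math.sqrt(2.0 * math.log(2.0)) / (math.pi * bw_mhz)


@dataclass(frozen=True)
class AcquisitionSpec:
    """Timing, gains and wavelength/steering program of one frame."""

    sampling_mhz: float = 40.0
    frame_rate_hz: float = 20.0
    pa_gain_db: float = 54.0
    us_gain_db: float = 39.0
    steer_angles_deg: tuple[float, ...] = (0.0, -10.0, 10.0)
    wavelengths_nm: tuple[float, ...] = (690.0, 756.0, 796.0, 820.0, 866.0)
    pa_us_delay_us: float = 100.0
    noise_rms: float = 0.0
    seed: int = 0

    def __post_init__(self):
        w = np.asarray(self.wavelengths_nm, dtype=float)
        if w.size and (np.any(np.diff(w) <= 0)):
            raise ValueError("wavelengths must be ascending and unique")
        if self.noise_rms < 0:
            raise ValueError("noise_rms must be non-negative")

    def validate_for(self, tx: TransducerSpec) -> None:
        if self.sampling_mhz <= 4.0 * tx.center_freq_mhz:
            raise ValueError("sampling rate must exceed 4x the center frequency")


@dataclass(frozen=True)
class BeamModel:
    """Illumination geometry of the fiber/diffuser relay.

    ``coaxial`` sends light through the transparent array at normal
    incidence; ``oblique`` is the conventional side-fired geometry (default
    45 degrees incidence from a fiber offset 4 mm from the imaging axis).
    """

    kind: str = "coaxial"
    fiber_diameter_mm: float = 1.0
    divergence_full_angle_deg: float = 40.0
    incidence_angle_deg: float | None = None
    standoff_offset_mm: float | None = None
    wavelength_nm: float = 750.0

    def __post_init__(self):
        if self.kind not in ("coaxial", "oblique"):
            raise ValueError("kind must be 'coaxial' or 'oblique'")
        if self.incidence_angle_deg is None:
            object.__setattr__(self, "incidence_angle_deg",
                               0.0 if self.kind == "coaxial" else 45.0)
        if self.standoff_offset_mm is None:
            object.__setattr__(self, "standoff_offset_mm",
                               0.0 if self.kind == "coaxial" else 4.0)
        if not 0.0 <= self.incidence_angle_deg < 90.0:
            raise ValueError("incidence angle must be in [0, 90) degrees")


@dataclass
class ChannelData:
    """Raw per-event receive traces: [event, element, sample]."""

    traces: np.ndarray
    modality: str                    # "PA" or "US"
    events: list[dict]               # per-event metadata
    sampling_mhz: float
    gain_db: float
    t0_s: float = 0.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.traces.ndim != 3:
            raise ValueError("traces must be [event, element, sample]")
        if len(self.events) != self.traces.shape[0]:
            raise ValueError("one metadata entry per event required")
        for ev in self.events:
            if self.modality == "PA" and "wavelength_nm" not in ev:
                raise ValueError("PA events carry wavelength_nm")
            if self.modality == "US" and "steer_angle_deg" not in ev:
                raise ValueError("US events carry steer_angle_deg")
            if "wavelength_nm" in ev and "steer_angle_deg" in ev:
                raise ValueError("events carry wavelength or angle, never both")

    @property
    def n_elements(self) -> int:
        return self.traces.shape[1]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[2]

    def times_us(self) -> np.ndarray:
        return self.t0_s * 1e6 + np.arange(self.n_samples) / self.sampling_mhz


# ---------------------------------------------------------------------------
# analytic fluence

def fluence_analytic(mua: np.ndarray, mus_prime: np.ndarray | float,
                     beam: BeamModel, grid: GridSpec,
                     edge_width_mm: float = 0.5) -> np.ndarray:
    """Broad-beam diffusion-approximation fluence on the phantom grid.

    Depth decay exp(-mu_eff * z_eff) with mu_eff = sqrt(3 mu_a (mu_a+mu_s'))
    from the depth-averaged coefficients; z_eff is the path length along the
    incidence direction; lateral profile is the (diverging) beam footprint:
    1 inside, Gaussian rolloff outside.  Maximum value 1.
    """
    mua = np.broadcast_to(np.asarray(mua, dtype=float), grid.shape)
    mus_prime = np.broadcast_to(np.asarray(mus_prime, dtype=float), grid.shape)
    if np.any(mua < 0) or np.any(mus_prime < 0):
        raise ValueError("optical coefficients must be non-negative")
    mua_bar = float(mua.mean())
    musp_bar = float(mus_prime.mean())
    mu_eff = math.sqrt(3.0 * mua_bar * (mua_bar + musp_bar))

    theta = math.radians(beam.incidence_angle_deg)
    X, Y, Z = np.meshgrid(grid.x_mm, grid.y_mm, grid.z_mm, indexing="ij")
    z_eff = Z / math.cos(theta)
    # beam axis enters at -standoff and tilts toward the imaging axis
    x_c = -beam.standoff_offset_mm + Z * math.tan(theta)
    radius = beam.fiber_diameter_mm / 2.0 + z_eff * math.tan(
        math.radians(beam.divergence_full_angle_deg) / 2.0)
    r = np.sqrt((X - x_c) ** 2 + Y ** 2)
    lateral = np.where(r <= radius, 1.0,
                       np.exp(-((r - radius) / edge_width_mm) ** 2))
    phi = np.exp(-mu_eff * z_eff) * lateral
    m = phi.max()
    return phi / m if m > 0 else phi


# ---------------------------------------------------------------------------
# pulse synthesis helpers

def _deposit_pulses(traces_2d: np.ndarray, delays_us: np.ndarray,
                    amps: np.ndarray, fc_mhz: float, sigma_us: float,
                    fs_mhz: float) -> bool:
    """Add Gaussian-enveloped tones at given delays into [element, sample].

    delays_us/amps are (n_elem, n_src); support truncated at +/- 4 sigma.
    Returns True if any pulse was truncated by the receive window.
    """
    n_elem, n_samp = traces_2d.shape
    half = 4.0 * sigma_us
    win = int(math.ceil(2.0 * half * fs_mhz)) + 1
    offsets = np.arange(win)
    truncated = False
    for e in range(n_elem):
        tau = delays_us[e]
        a = amps[e]
        keep = a != 0.0
        if not np.any(keep):
            continue
        tau = tau[keep]
        a = a[keep]
        idx0 = np.floor((tau - half) * fs_mhz).astype(np.int64)
        idx = idx0[:, None] + offsets[None, :]
        t = idx / fs_mhz - tau[:, None]
        vals = a[:, None] * np.cos(2 * np.pi * fc_mhz * t) * np.exp(
            -0.5 * (t / sigma_us) ** 2)
        inside = (idx >= 0) & (idx < n_samp)
        if not inside.all():
            if np.any(~inside & (np.abs(vals) > 0)):
                truncated = True
        np.add.at(traces_2d[e], idx[inside], vals[inside])
    return truncated


def _default_n_samples(max_range_mm: float, c_mm_us: float, sigma_us: float,
                       fs_mhz: float) -> int:
    return int(math.ceil((max_range_mm / c_mm_us + 6.0 * sigma_us) * fs_mhz))


# ---------------------------------------------------------------------------
# photoacoustic forward model

def pa_channel_data(phantom: DigitalPhantom, fluence: np.ndarray,
                    tx: TransducerSpec, acq: AcquisitionSpec,
                    wavelength_nm: float, spectra: SpectraTable | None = None,
                    slice_iy: int | None = None, n_samples: int | None = None,
                    gruneisen: float = 1.0,
                    rng: np.random.Generator | None = None) -> ChannelData:
    """One-wavelength PA receive event for one elevational slice.

    Each source voxel contributes a band-limited pulse delayed by r/c and
    scaled by p0/r, with a hard +/-45 degree element acceptance angle.
    Additive white Gaussian noise at ``acq.noise_rms`` (pre-gain units) and
    the PA receive gain are applied before return.
    """
    acq.validate_for(tx)
    spectra = spectra or SpectraTable.default()
    grid = phantom.grid
    if fluence.shape != grid.shape:
        raise ValueError("fluence must be co-registered with the phantom")
    iy = grid.shape[1] // 2 if slice_iy is None else slice_iy

    p0 = gruneisen * chromophore_mua(phantom, wavelength_nm, spectra)[:, iy, :] \
        * fluence[:, iy, :]
    c = phantom.sound_speed_mps / 1000.0  # mm/us
    sigma = tx.pulse_sigma_us
    elem_x = tx.element_x_mm()
    max_range = math.hypot(grid.extent_mm[0] / 2 + tx.aperture_mm / 2,
                           grid.extent_mm[2])
    n_samp = n_samples or _default_n_samples(max_range, c, sigma, acq.sampling_mhz)

    traces = np.zeros((1, tx.n_elements, n_samp))
    src = np.argwhere(p0 > 0)
    truncated = False
    if src.size:
        xs = grid.x_mm[src[:, 0]]
        zs = grid.z_mm[src[:, 1]]
        amp0 = p0[src[:, 0], src[:, 1]]
        dx = xs[None, :] - elem_x[:, None]
        r = np.sqrt(dx ** 2 + zs[None, :] ** 2)
        r = np.maximum(r, grid.voxel_size_mm)
        accept = np.abs(dx) <= zs[None, :] * math.tan(
            math.radians(DIRECTIVITY_HALF_ANGLE_DEG))
        amps = np.where(accept, amp0[None, :] / r, 0.0)
        truncated = _deposit_pulses(traces[0], r / c, amps,
                                    tx.center_freq_mhz, sigma, acq.sampling_mhz)

    rng = rng or np.random.default_rng(acq.seed)
    if acq.noise_rms > 0:
        traces += rng.normal(0.0, acq.noise_rms, size=traces.shape)
    traces *= 10.0 ** (acq.pa_gain_db / 20.0)

    prov = {"generator": "pa_channel_data", "seed": acq.seed,
            "wavelength_nm": wavelength_nm, "slice_iy": iy,
            "gruneisen": gruneisen, "truncated": truncated,
            "transducer": asdict(tx), "acquisition": asdict(acq)}
    events = [{"modality": "PA", "wavelength_nm": float(wavelength_nm),
               "t0_s": 0.0}]
    return ChannelData(traces=traces, modality="PA", events=events,
                       sampling_mhz=acq.sampling_mhz, gain_db=acq.pa_gain_db,
                       provenance=prov)


# ---------------------------------------------------------------------------
# ultrasound forward model

MAX_STEER_DEG = 30.0


def us_channel_data(phantom: DigitalPhantom, tx: TransducerSpec,
                    acq: AcquisitionSpec, angle_deg: float,
                    slice_iy: int | None = None, n_samples: int | None = None,
                    beam_sigma_mm: float = 0.4,
                    rng: np.random.Generator | None = None) -> ChannelData:
    """One steered line-beam packet: 64 transmitted lines, one event each.

    The transmit wavefront of line l is modeled as spherical from the line
    origin (element position x_l), laterally confined to a Gaussian profile
    around the steered line axis; receive is per element.  Two-way delay
    (r_tx + r_rx)/c and 1/r spreading each way; this keeps transmit/receive
    arrival times reciprocal under exchanging element roles.
    """
    if abs(angle_deg) > MAX_STEER_DEG:
        raise ValueError(f"steer angle {angle_deg} beyond +/-{MAX_STEER_DEG} deg")
    acq.validate_for(tx)
    grid = phantom.grid
    iy = grid.shape[1] // 2 if slice_iy is None else slice_iy
    scat = phantom.scatter_amp[:, iy, :]

    c = phantom.sound_speed_mps / 1000.0
    sigma = tx.pulse_sigma_us
    elem_x = tx.element_x_mm()
    max_range = math.hypot(grid.extent_mm[0] / 2 + tx.aperture_mm / 2,
                           grid.extent_mm[2])
    n_samp = n_samples or _default_n_samples(2.0 * max_range, c, sigma,
                                             acq.sampling_mhz)
    n_lines = tx.n_elements
    traces = np.zeros((n_lines, tx.n_elements, n_samp))

    src = np.argwhere(scat != 0)
    truncated = False
    if src.size:
        xs = grid.x_mm[src[:, 0]]
        zs = grid.z_mm[src[:, 1]]
        amp0 = scat[src[:, 0], src[:, 1]]
        th = math.radians(angle_deg)
        dx_rx = xs[None, :] - elem_x[:, None]           # (elem, src)
        r_rx = np.maximum(np.sqrt(dx_rx ** 2 + zs[None, :] ** 2),
                          grid.voxel_size_mm)
        accept = np.abs(dx_rx) <= zs[None, :] * math.tan(
            math.radians(DIRECTIVITY_HALF_ANGLE_DEG))
        for l in range(n_lines):
            dxl = xs - elem_x[l]
            r_tx = np.maximum(np.sqrt(dxl ** 2 + zs ** 2), grid.voxel_size_mm)
            # perpendicular distance from the steered line axis
            d_perp = dxl * math.cos(th) - zs * math.sin(th)
            w = np.exp(-0.5 * (d_perp / beam_sigma_mm) ** 2)
            a_src = amp0 * w / r_tx
            keep = w > 1e-3
            if not np.any(keep):
                continue
            delays = (r_tx[None, keep] + r_rx[:, keep]) / c
            amps = np.where(accept[:, keep],
                            a_src[None, keep] / r_rx[:, keep], 0.0)
            truncated |= _deposit_pulses(traces[l], delays, amps,
                                         tx.center_freq_mhz, sigma,
                                         acq.sampling_mhz)

    rng = rng or np.random.default_rng(acq.seed + 1)
    if acq.noise_rms > 0:
        traces += rng.normal(0.0, acq.noise_rms, size=traces.shape)
    traces *= 10.0 ** (acq.us_gain_db / 20.0)

    prov = {"generator": "us_channel_data", "seed": acq.seed,
            "steer_angle_deg": angle_deg, "slice_iy": iy,
            "beam_sigma_mm": beam_sigma_mm, "truncated": truncated,
            "transducer": asdict(tx), "acquisition": asdict(acq)}
    events = [{"modality": "US", "steer_angle_deg": float(angle_deg),
               "line_index": l, "line_x_mm": float(elem_x[l]), "t0_s": 0.0}
              for l in range(n_lines)]
    return ChannelData(traces=traces, modality="US", events=events,
                       sampling_mhz=acq.sampling_mhz, gain_db=acq.us_gain_db,
                       provenance=prov)


# ---------------------------------------------------------------------------
# fluorescence camera model

ICG_EXCITATION_BAND_NM = (650.0, 850.0)


def fluorescence_frame(phantom: DigitalPhantom, excitation_nm: float = 756.0,
                       atten_per_mm: float = 0.5) -> np.ndarray:
    """En-face NIR fluorescence image: depth-weighted vertical projection.

    pixel(x, y) = sum_z ICG(x, y, z) * exp(-2 * atten_per_mm * z) * dz,
    the factor 2 accounting for round-trip (excitation + emission)
    attenuation.  Emission is conceptually band-passed to 800-900 nm; the
    camera optics are not modeled.
    """
    lo, hi = ICG_EXCITATION_BAND_NM
    if not lo <= excitation_nm <= hi:
        raise ValueError(f"excitation {excitation_nm} nm outside ICG band {lo}-{hi}")
    if atten_per_mm < 0:
        raise ValueError("atten_per_mm must be non-negative")
    z = phantom.grid.z_mm
    w = np.exp(-2.0 * atten_per_mm * z)
    return (phantom.conc["ICG"] * w[None, None, :]).sum(axis=2) \
        * phantom.grid.voxel_size_mm


def fl_detection_depth_mm(atten_per_mm: float = 0.5, noise_rel: float = 1e-3,
                          snr_floor_db: float = 6.0) -> float:
    """Depth at which tube contrast falls to the SNR floor above camera noise.

    Solves 20 log10(exp(-2 a d) / noise_rel) = snr_floor_db for d.
    """
    if atten_per_mm <= 0:
        raise ValueError("atten_per_mm must be positive")
    return (math.log(1.0 / noise_rel) - snr_floor_db * math.log(10) / 20.0) \
        / (2.0 * atten_per_mm)
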