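"""Digital phantoms for the trimodal imaging chain.

Scenes are voxel grids of chromophore concentration (Hb, HbO2, ICG), acoustic
scatterer amplitude (fully developed speckle) and optical background
properties.  Vessels and lymphatics are tubes around polyline centerlines;
arteries can be modulated in time with a raised-cosine systolic pulse train.

Coordinates: x lateral (element axis, centered on the array), y elevational
(centered), z axial depth with z = 0 at the transducer face.  Millimetres
everywhere; voxel centers at half-integer offsets (half-open voxel extents).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .spectra import SpectraTable

SPECIES = ("Hb", "HbO2", "ICG")


class BoundsError(ValueError):
    """A vessel extends outside the phantom grid."""


class ResolutionError(ValueError):
    """A vessel is too thin for the voxel grid (radius < 2 voxels)."""


@dataclass(frozen=True)
class GridSpec:
    """Voxel grid geometry: shape (nx, ny, nz), isotropic voxel size in mm."""

    shape: tuple[int, int, int]
    voxel_size_mm: float

    def __post_init__(self):
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError("shape must be three positive integers")

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * self.voxel_size_mm for n in self.shape)

    @property
    def x_mm(self) -> np.ndarray:
        nx = self.shape[0]
        return (np.arange(nx) + 0.5) * self.voxel_size_mm - self.extent_mm[0] / 2

    @property
    def y_mm(self) -> np.ndarray:
        ny = self.shape[1]
        return (np.arange(ny) + 0.5) * self.voxel_size_mm - self.extent_mm[1] / 2

    @property
    def z_mm(self) -> np.ndarray:
        return (np.arange(self.shape[2]) + 0.5) * self.voxel_size_mm

    def centers(self) -> np.ndarray:
        """(nx*ny*nz, 3) array of voxel-center coordinates."""
        X, Y, Z = np.meshgrid(self.x_mm, self.y_mm, self.z_mm, indexing="ij")
        return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)


@dataclass(frozen=True)
class Background:
    """Optical/acoustic background of the medium."""

    mu_a_mm: float = 0.01           # background absorption, mm^-1
    mu_s_prime_mm: float = 1.0      # reduced scattering, mm^-1
    scatter_density_per_mm3: float = 2.0
    scatter_amp_sigma: float = 1.0  # Gaussian scatterer amplitude std


@dataclass(frozen=True)
class VesselSpec:
    """Tube around a polyline centerline.

    ``species_mix`` maps species name to concentration (mol/L, relative scale
    allowed).  For blood vessels ``so2`` must equal HbO2/(Hb+HbO2) of the mix.
    """

    centerline: np.ndarray          # (N, 3) points, mm
    radius_mm: float
    species_mix: Mapping[str, float]
    so2: float | None = None
    arterial: bool = False

    def __post_init__(self):
        object.__setattr__(self, "centerline",
                           np.atleast_2d(np.asarray(self.centerline, dtype=float)))
        if self.centerline.shape[1] != 3:
            raise ValueError("centerline must be (N, 3) points in mm")
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        total = sum(self.species_mix.values())
        if total <= 0 or any(v < 0 for v in self.species_mix.values()):
            raise ValueError("species_mix must be non-negative with positive total")
        hb = self.species_mix.get("Hb", 0.0)
        hbo2 = self.species_mix.get("HbO2", 0.0)
        if hb + hbo2 > 0:
            so2_mix = hbo2 / (hb + hbo2)
            if self.so2 is None:
                object.__setattr__(self, "so2", so2_mix)
            elif abs(so2_mix - self.so2) > 1e-12:
                raise ValueError(
                    f"so2={self.so2} inconsistent with mix (implies {so2_mix})")

    @property
    def depth_mm(self) -> float:
        """Mean axial position of the centerline."""
        return float(np.mean(self.centerline[:, 2]))


def blood_mix(total_molar: float, so2: float) -> dict[str, float]:
    """Hb/HbO2 concentration split at a given oxygen saturation."""
    if not 0.0 <= so2 <= 1.0:
        raise ValueError("so2 must be in [0, 1]")
    return {"Hb": total_molar * (1.0 - so2), "HbO2": total_molar * so2}


@dataclass(frozen=True)
class DynamicsSpec:
    """Pulsatile arterial dynamics of a framed acquisition."""

    heart_rate_bpm: float
    modulation_depth: float = 0.1
    frame_rate_hz: float = 20.0
    n_frames: int = 200
    duty: float = 0.35  # systolic pulse width as a fraction of the beat

    def __post_init__(self):
        if self.heart_rate_bpm <= 0 or self.frame_rate_hz <= 0 or self.n_frames < 1:
            raise ValueError("rates and frame count must be positive")
        if not 0.0 <= self.modulation_depth < 1.0:
            raise ValueError("modulation_depth must be in [0, 1)")
        if self.heart_rate_bpm / 60.0 >= self.frame_rate_hz / 2.0:
            raise ValueError(
                f"heart rate {self.heart_rate_bpm} bpm violates Nyquist at "
                f"{self.frame_rate_hz} Hz frame rate")

    @property
    def fundamental_hz(self) -> float:
        return self.heart_rate_bpm / 60.0


def raised_cosine_train(phase, duty: float = 0.35) -> np.ndarray:
    """Zero-mean periodic systolic pulse train, peak value 1.

    ``phase`` is in cycles.  Within each cycle the first ``duty`` fraction is
    a raised-cosine bump, the rest is diastolic rest; the mean is subtracted
    and the result rescaled to unit peak.  The sharp bump carries harmonics,
    unlike a pure sinusoid.
    """
    if not 0.0 < duty <= 1.0:
        raise ValueError("duty must be in (0, 1]")
    ph = np.mod(np.asarray(phase, dtype=float), 1.0)
    p = np.where(ph < duty, 0.5 * (1.0 - np.cos(2.0 * np.pi * ph / duty)), 0.0)
    return (p - duty / 2.0) / (1.0 - duty / 2.0)


@dataclass
class DigitalPhantom:
    """Voxelized scene: concentrations, speckle scatterers, background."""

    grid: GridSpec
    conc: dict[str, np.ndarray]
    scatter_amp: np.ndarray
    background: Background
    sound_speed_mps: float = 1540.0
    vessels: tuple[VesselSpec, ...] = ()
    seed: int = 0

    def __post_init__(self):
        for s, g in self.conc.items():
            if g.shape != self.grid.shape:
                raise ValueError(f"conc[{s}] shape {g.shape} != grid {self.grid.shape}")
            if np.any(g < 0):
                raise ValueError(f"conc[{s}] has negative values")
        if self.scatter_amp.shape != self.grid.shape:
            raise ValueError("scatter_amp shape mismatch")

    @property
    def mu_s_prime_background(self) -> float:
        return self.background.mu_s_prime_mm

    def total(self, species: str) -> float:
        """Total substance amount: sum(conc) * voxel volume."""
        return float(self.conc[species].sum() * self.grid.voxel_size_mm ** 3)


def _segment_distances(points: np.ndarray, centerline: np.ndarray) -> np.ndarray:
    """Min distance from each point to a polyline (brute force over segments)."""
    if centerline.shape[0] == 1:
        return np.linalg.norm(points - centerline[0], axis=1)
    dmin = np.full(points.shape[0], np.inf)
    for a, b in zip(centerline[:-1], centerline[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0.0:
            d = np.linalg.norm(points - a, axis=1)
        else:
            t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
            d = np.linalg.norm(points - a - t[:, None] * ab, axis=1)
        np.minimum(dmin, d, out=dmin)
    return dmin


def _check_vessel(v: VesselSpec, grid: GridSpec) -> None:
    if v.radius_mm < 2.0 * grid.voxel_size_mm:
        raise ResolutionError(
            f"vessel radius {v.radius_mm} mm < 2 voxels "
            f"({2 * grid.voxel_size_mm} mm)")
    ex, ey, ez = grid.extent_mm
    lo = np.array([-ex / 2, -ey / 2, 0.0])
    hi = np.array([ex / 2, ey / 2, ez])
    # 2.5-D slab (single elevational slice): the tube may cross the slab
    margin = np.array([v.radius_mm,
                       v.radius_mm if grid.shape[1] > 1 else 0.0,
                       v.radius_mm])
    pts = v.centerline
    if np.any(pts - margin < lo) or np.any(pts + margin > hi):
        raise BoundsError(
            f"vessel (radius {v.radius_mm} mm) extends outside grid extents "
            f"x[{lo[0]},{hi[0]}] y[{lo[1]},{hi[1]}] z[{lo[2]},{hi[2]}] mm")


def make_phantom(vessels: Sequence[VesselSpec],
                 grid: GridSpec,
                 background: Background | None = None,
                 seed: int = 0,
                 sound_speed_mps: float = 1540.0) -> DigitalPhantom:
    """Rasterize tube vessels onto a voxel grid and seed acoustic speckle.

    Voxels whose center lies within a vessel radius of its centerline carry
    that vessel's species mix (later vessels overwrite earlier ones where
    tubes overlap).  Speckle scatterers are uniform random sub-voxel points
    with Gaussian amplitudes, accumulated onto the grid; deterministic for a
    given seed.
    """
    background = background or Background()
    conc = {s: np.zeros(grid.shape) for s in SPECIES}
    centers = grid.centers()
    for v in vessels:
        _check_vessel(v, grid)
        inside = (_segment_distances(centers, v.centerline)
                  <= v.radius_mm).reshape(grid.shape)
        for s in SPECIES:
            conc[s][inside] = v.species_mix.get(s, 0.0)

    rng = np.random.default_rng(seed)
    scatter = np.zeros(grid.shape)
    n_scat = int(round(background.scatter_density_per_mm3 * np.prod(grid.extent_mm)))
    if n_scat > 0:
        idx = np.floor(rng.uniform(0, 1, size=(n_scat, 3))
                       * np.array(grid.shape)).astype(int)
        amps = rng.normal(0.0, background.scatter_amp_sigma, size=n_scat)
        np.add.at(scatter, (idx[:, 0], idx[:, 1], idx[:, 2]), amps)
    scatter = np.abs(scatter)  # echogenicity is non-negative

    return DigitalPhantom(grid=grid, conc=conc, scatter_amp=scatter,
                          background=background, sound_speed_mps=sound_speed_mps,
                          vessels=tuple(vessels), seed=seed)


def chromophore_mua(phantom: DigitalPhantom, wavelength_nm: float,
                    spectra: SpectraTable) -> np.ndarray:
    """Absorption from chromophores only (mm^-1), the photoacoustic source term."""
    mua = np.zeros(phantom.grid.shape)
    for s in SPECIES:
        if s in spectra.species:
            mua += spectra.mua_mm(s, phantom.conc[s], wavelength_nm)
    return mua


def absorption_map(phantom: DigitalPhantom, wavelength_nm: float,
                   spectra: SpectraTable) -> np.ndarray:
    """Total absorption coefficient grid (mm^-1): background + chromophores.

    Linear in concentrations; raises if the wavelength is outside the
    spectra table coverage (no extrapolation).
    """
    return phantom.background.mu_a_mm + chromophore_mua(phantom, wavelength_nm, spectra)


def modulate_pulsatile(phantom: DigitalPhantom, dynamics: DynamicsSpec,
                       frame_index: int) -> DigitalPhantom:
    """Snapshot of the phantom at one frame of a pulsatile acquisition.

    Arterial vessel radius and concentration are scaled by
    ``1 + modulation_depth * s(f0 * t)`` with s the zero-mean raised-cosine
    pulse train; everything else (including the speckle seed) is unchanged,
    so non-arterial voxels are identical to the static phantom.
    """
    if not 0 <= frame_index < dynamics.n_frames:
        raise ValueError(f"frame_index {frame_index} outside [0, {dynamics.n_frames})")
    t = frame_index / dynamics.frame_rate_hz
    scale = 1.0 + dynamics.modulation_depth * float(
        raised_cosine_train(dynamics.fundamental_hz * t, dynamics.duty))
    if not any(v.arterial for v in phantom.vessels):
        return phantom
    vessels = []
    for v in phantom.vessels:
        if v.arterial:
            mix = {s: c * scale for s, c in v.species_mix.items()}
            vessels.append(replace(v, radius_mm=v.radius_mm * scale,
                                   species_mix=mix))
        else:
            vessels.append(v)
    return make_phantom(vessels, phantom.grid, phantom.background,
                        seed=phantom.seed, sound_speed_mps=phantom.sound_speed_mps)
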