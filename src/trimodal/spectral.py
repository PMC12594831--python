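"""Fluence compensation, pseudo-inverse spectral unmixing and sO2 mapping.

Multispectral PA images are first corrected for the depth decay of optical
fluence, then decomposed per pixel into chromophore concentrations with the
unconstrained least-squares pseudo-inverse

    [C_1 ... C_n] = [PA_1 ... PA_k] . M^T . (M . M^T)^-1,

where row n of M is the normalized absorption spectrum of species n sampled
at the k acquisition wavelengths.  Oxygen saturation is the HbO2 fraction of
total hemoglobin, masked where total hemoglobin is below threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .spectra import SpectraTable


class DegeneracyError(ValueError):
    """Species spectra are collinear at the chosen wavelengths."""


@dataclass
class SpectralStack:
    """Co-registered linear-amplitude PA images across wavelengths [w, z, x]."""

    images: np.ndarray
    wavelengths_nm: np.ndarray
    compensated: bool = False
    pixel_size_mm: float = 0.1
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("images must be [wavelength, z, x]")
        if self.images.shape[0] != self.wavelengths_nm.size:
            raise ValueError("one image per wavelength required")
        if np.unique(self.wavelengths_nm).size != self.wavelengths_nm.size:
            raise ValueError("wavelengths must be distinct")


@dataclass
class UnmixedMaps:
    """Per-species concentration images plus the derived sO2 map."""

    conc: dict[str, np.ndarray]
    so2: np.ndarray | None = None           # masked array once filled
    threshold_used: float | None = None
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# fluence compensation

def fluence_compensate(stack: SpectralStack,
                       object_mask: np.ndarray | None = None,
                       background_percentile: float = 20.0,
                       min_background_pixels: int = 8) -> SpectralStack:
    """Normalize the depth decay of fluence out of each wavelength image.

    Per wavelength: the background level b(z) of each depth row is the
    ``background_percentile``-th percentile over non-object pixels; a single
    exponential A*exp(-k z) is fit to b(z) (log-linear least squares,
    monotone decay enforced) and every pixel of the row is divided by the
    fitted curve normalized to 1 at z = 0.  Rows with too few background
    pixels are excluded from the fit (with a warning) but still corrected by
    the global fit.
    """
    if stack.compensated:
        raise ValueError("stack is already compensated")
    if not np.any(stack.images != 0):
        raise ValueError("all-zero stack: nothing to compensate")
    n_w, nz, nx = stack.images.shape
    if object_mask is not None and object_mask.shape != (nz, nx):
        raise ValueError("object_mask must match image shape")
    bg_mask = (~object_mask) if object_mask is not None \
        else np.ones((nz, nx), dtype=bool)
    z = (np.arange(nz) + 0.5) * stack.pixel_size_mm

    out = np.empty_like(stack.images)
    fits = []
    for i in range(n_w):
        img = stack.images[i]
        b = np.full(nz, np.nan)
        short_rows = 0
        for iz in range(nz):
            vals = img[iz][bg_mask[iz]]
            if vals.size < min_background_pixels:
                short_rows += 1
                continue
            b[iz] = np.percentile(vals, background_percentile)
        if short_rows:
            warnings.warn(f"{short_rows} rows with < {min_background_pixels} "
                          "background pixels; excluded from the decay fit")
        ok = np.isfinite(b) & (b > 0)
        if ok.sum() >= 2:
            coef = np.polyfit(z[ok], np.log(b[ok]), 1)
            k = max(-coef[0], 0.0)  # enforce monotone decay
        else:
            warnings.warn("insufficient background rows; no decay estimated")
            k = 0.0
        curve = np.exp(-k * z)  # normalized to ~1 at z=0
        out[i] = img / curve[:, None]
        fits.append({"wavelength_nm": float(stack.wavelengths_nm[i]),
                     "decay_per_mm": float(k)})
    prov = dict(stack.provenance)
    prov["fluence_fits"] = fits
    prov["background_percentile"] = background_percentile
    return SpectralStack(images=out, wavelengths_nm=stack.wavelengths_nm,
                         compensated=True, pixel_size_mm=stack.pixel_size_mm,
                         provenance=prov)


# ---------------------------------------------------------------------------
# unmixing

def build_M(spectra: SpectraTable, wavelengths_nm, species,
            normalize: bool = True) -> np.ndarray:
    """Species x wavelength absorption matrix, rows at unit maximum.

    Requires at least as many wavelengths as species and a full-rank result;
    a rank-deficient matrix raises DegeneracyError naming the most collinear
    species pair.
    """
    wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
    species = list(species)
    if wavelengths_nm.size < len(species):
        raise ValueError("need at least as many wavelengths as species")
    M = np.stack([np.asarray(spectra.epsilon(s, wavelengths_nm), dtype=float)
                  for s in species])
    if normalize:
        row_max = M.max(axis=1, keepdims=True)
        if np.any(row_max <= 0):
            bad = [s for s, m in zip(species, row_max[:, 0]) if m <= 0]
            raise DegeneracyError(f"species {bad} have zero spectrum here")
        M = M / row_max
    if np.linalg.matrix_rank(M, tol=1e-10 * np.abs(M).max()) < len(species):
        # name the most collinear pair
        norms = np.linalg.norm(M, axis=1)
        C = (M / norms[:, None]) @ (M / norms[:, None]).T
        np.fill_diagonal(C, 0.0)
        i, j = np.unravel_index(np.abs(C).argmax(), C.shape)
        raise DegeneracyError(
            f"rank-deficient spectra matrix: {species[i]} and {species[j]} "
            f"are collinear at these wavelengths")
    return M


def unmix(stack: SpectralStack, M: np.ndarray,
          species: list[str] | None = None,
          require_compensated: bool = True) -> UnmixedMaps:
    """Pseudo-inverse unmixing: C = PA . M^T . (M M^T)^-1 per pixel.

    Negative concentrations are retained (diagnostic); they are clamped only
    when forming the sO2 ratio or for display.
    """
    if require_compensated and not stack.compensated:
        raise ValueError("stack must be fluence-compensated before unmixing")
    M = np.asarray(M, dtype=float)
    n_species, k = M.shape
    if stack.images.shape[0] != k:
        raise ValueError("stack wavelengths must match M columns")
    MMt = M @ M.T
    if np.linalg.matrix_rank(MMt, tol=1e-12 * np.abs(MMt).max()) < n_species:
        raise DegeneracyError("M . M^T is singular")
    pinv = M.T @ np.linalg.inv(MMt)            # (k, n)
    nw, nz, nx = stack.images.shape
    pa = stack.images.reshape(nw, -1).T        # (pixels, k)
    conc = (pa @ pinv).T.reshape(n_species, nz, nx)
    names = species or [f"species_{i}" for i in range(n_species)]
    prov = dict(stack.provenance)
    prov["unmixing"] = "pseudo-inverse"
    return UnmixedMaps(conc={s: conc[i] for i, s in enumerate(names)},
                       provenance=prov)


def so2_map(maps: UnmixedMaps, total_hb_threshold: float | None = None) -> UnmixedMaps:
    """Fill the sO2 map: m_HbO2 / (m_HbO2 + m_Hb), negatives clamped first.

    Pixels with total hemoglobin below threshold are masked.  The default
    threshold is 5% of the 99th-percentile total-hemoglobin amplitude.
    """
    if "Hb" not in maps.conc or "HbO2" not in maps.conc:
        raise ValueError("need unmixed Hb and HbO2 maps")
    hb = np.clip(maps.conc["Hb"], 0.0, None)
    hbo2 = np.clip(maps.conc["HbO2"], 0.0, None)
    total = hb + hbo2
    if total_hb_threshold is None:
        total_hb_threshold = 0.05 * np.percentile(total, 99)
    masked = total < total_hb_threshold
    with np.errstate(divide="ignore", invalid="ignore"):
        so2 = np.where(total > 0, hbo2 / np.where(total > 0, total, 1.0), 0.0)
    maps.so2 = np.ma.MaskedArray(so2, mask=masked)
    maps.threshold_used = float(total_hb_threshold)
    return maps
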