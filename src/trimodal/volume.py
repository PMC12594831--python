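"""3-D mosaic assembly and projection products.

Overlapping linear scan lanes (stacks of elevationally stepped B-scans) are
stitched into one volume with linear feathering across the lateral overlap,
then rendered as maximum amplitude projections (MAP), depth-encoded MAPs and
PA-over-US composites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from matplotlib import colormaps

from .recon import BScanImage

DEPTH_COLORMAP = "viridis"  # perceptually uniform; hue monotone in depth


class GapError(ValueError):
    """Adjacent lanes do not overlap."""


@dataclass
class ScanLane:
    """Ordered B-scan slices of one linear scan at stepped y positions."""

    slices: np.ndarray              # [y, z, x]
    pixel_size_mm: float
    y_start_mm: float = 0.0
    y_step_mm: float = 0.5
    lane_x_offset_mm: float = 0.0

    def __post_init__(self):
        self.slices = np.asarray(self.slices, dtype=float)
        if self.slices.ndim != 3:
            raise ValueError("slices must be [y, z, x]")
        if self.y_step_mm <= 0:
            raise ValueError("y_step_mm must be positive")

    @classmethod
    def from_bscans(cls, bscans: Sequence[BScanImage], y_start_mm: float = 0.0,
                    y_step_mm: float = 0.5, lane_x_offset_mm: float = 0.0
                    ) -> "ScanLane":
        px = bscans[0].pixel_size_mm
        shape = bscans[0].pixels.shape
        for b in bscans:
            if b.pixels.shape != shape or b.pixel_size_mm != px:
                raise ValueError("inconsistent slice geometry")
        return cls(slices=np.stack([b.pixels for b in bscans]),
                   pixel_size_mm=px, y_start_mm=y_start_mm,
                   y_step_mm=y_step_mm, lane_x_offset_mm=lane_x_offset_mm)

    @property
    def x_span_mm(self) -> float:
        return self.slices.shape[2] * self.pixel_size_mm

    @property
    def x_min_mm(self) -> float:
        return self.lane_x_offset_mm - self.x_span_mm / 2

    @property
    def x_max_mm(self) -> float:
        return self.lane_x_offset_mm + self.x_span_mm / 2


@dataclass
class Volume3D:
    """Stitched volume, voxels indexed [z, y, x]."""

    voxels: np.ndarray
    voxel_size_mm: float
    y_step_mm: float
    x_min_mm: float = 0.0
    y_min_mm: float = 0.0
    channel: str = "PA"
    provenance: dict = field(default_factory=dict)

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        nz, ny, nx = self.voxels.shape
        return (nx * self.voxel_size_mm, ny * self.y_step_mm,
                nz * self.voxel_size_mm)


def stitch_mosaic(lanes: Sequence[ScanLane], blend: str = "feather",
                  channel: str = "PA",
                  min_overlap_mm: float = 1.0) -> Volume3D:
    """Stitch overlapping lanes into one mosaic volume.

    Lane registration is by stage coordinates only.  In the lateral overlap
    between consecutive lanes, voxels are combined by linear feathering over
    the full overlap width (weights sum to 1); elsewhere voxels are copied.
    """
    if not lanes:
        raise ValueError("no lanes given")
    px = lanes[0].pixel_size_mm
    nz = lanes[0].slices.shape[1]
    ny = lanes[0].slices.shape[0]
    ystep = lanes[0].y_step_mm
    for ln in lanes:
        if ln.pixel_size_mm != px or ln.slices.shape[1] != nz:
            raise ValueError("lanes must share z grid and pixel size")
        if ln.slices.shape[0] != ny or ln.y_step_mm != ystep:
            raise ValueError("lanes must share elevational sampling")
    lanes = sorted(lanes, key=lambda ln: ln.lane_x_offset_mm)
    for a, b in zip(lanes[:-1], lanes[1:]):
        overlap = a.x_max_mm - b.x_min_mm
        if overlap < min_overlap_mm:
            raise GapError(
                f"lanes at x offsets {a.lane_x_offset_mm} and "
                f"{b.lane_x_offset_mm} mm overlap {overlap:.2f} mm "
                f"(< {min_overlap_mm} mm)")

    x_min = min(ln.x_min_mm for ln in lanes)
    x_max = max(ln.x_max_mm for ln in lanes)
    nx = int(round((x_max - x_min) / px))
    acc = np.zeros((nz, ny, nx))
    wsum = np.zeros(nx)

    if blend not in ("feather", "mean"):
        raise ValueError("blend must be 'feather' or 'mean'")
    for i, ln in enumerate(lanes):
        nxl = ln.slices.shape[2]
        w = np.ones(nxl)
        if blend == "feather":
            if i > 0:
                ov = lanes[i - 1].x_max_mm - ln.x_min_mm
                n_ov = int(round(ov / px))
                if n_ov > 0:
                    w[:n_ov] = np.minimum(w[:n_ov],
                                          (np.arange(n_ov) + 0.5) / n_ov)
            if i < len(lanes) - 1:
                ov = ln.x_max_mm - lanes[i + 1].x_min_mm
                n_ov = int(round(ov / px))
                if n_ov > 0:
                    w[nxl - n_ov:] = np.minimum(
                        w[nxl - n_ov:], ((np.arange(n_ov) + 0.5) / n_ov)[::-1])
        i0 = int(round((ln.x_min_mm - x_min) / px))
        acc[:, :, i0:i0 + nxl] += np.transpose(ln.slices, (1, 0, 2)) * w
        wsum[i0:i0 + nxl] += w
    if np.any(wsum <= 0):
        raise GapError("stitched extent has uncovered columns")
    acc /= wsum[None, None, :]

    return Volume3D(voxels=acc, voxel_size_mm=px, y_step_mm=ystep,
                    x_min_mm=x_min, y_min_mm=lanes[0].y_start_mm,
                    channel=channel,
                    provenance={"n_lanes": len(lanes), "blend": blend,
                                "feather_weights_sum_to_one": True})


def feather_weight_sum(lanes: Sequence[ScanLane]) -> np.ndarray:
    """Normalized blending weight total per output column (should be 1)."""
    vol = stitch_mosaic(lanes)
    ones = [ScanLane(np.ones_like(ln.slices), ln.pixel_size_mm, ln.y_start_mm,
                     ln.y_step_mm, ln.lane_x_offset_mm) for ln in lanes]
    return stitch_mosaic(ones).voxels[0, 0, :]


def map_projection(volume: Volume3D) -> np.ndarray:
    """Maximum amplitude projection: pixel(y, x) = max_z |voxel|."""
    if volume.voxels.size == 0:
        raise ValueError("empty volume")
    return np.abs(volume.voxels).max(axis=0)


def depth_encode(volume: Volume3D, z_range_mm: tuple[float, float] = (0.0, 10.0),
                 colormap: str = DEPTH_COLORMAP) -> tuple[np.ndarray, dict]:
    """Depth-encoded MAP: hue = argmax depth, value = MAP amplitude.

    Returns an RGBA image [y, x, 4] plus colorbar metadata.  The hue of each
    column is the depth of its amplitude maximum mapped linearly over
    ``z_range_mm`` through a perceptually uniform colormap; the color is
    scaled by the normalized MAP amplitude.  Empty columns are transparent.
    """
    z0, z1 = z_range_mm
    nz = volume.voxels.shape[0]
    z_ext = nz * volume.voxel_size_mm
    if not (0.0 <= z0 < z1 <= z_ext + 1e-9):
        raise ValueError(f"z_range {z_range_mm} outside volume extent [0, {z_ext}]")
    amp = np.abs(volume.voxels)
    m = map_projection(volume)
    iz = amp.argmax(axis=0)
    depth = (iz + 0.5) * volume.voxel_size_mm
    frac = np.clip((depth - z0) / (z1 - z0), 0.0, 1.0)
    cmap = colormaps[colormap]
    rgba = cmap(frac)
    peak = m.max()
    val = m / peak if peak > 0 else m
    rgba[..., :3] *= val[..., None]
    rgba[..., 3] = np.where(m > 0, 1.0, 0.0)  # empty columns transparent
    meta = {"colormap": colormap, "z_range_mm": [z0, z1],
            "hue_monotone_in_depth": True}
    return rgba, meta


FIXED_SPECIES_COLORS = {"ICG": (0.0, 1.0, 0.0),     # green, lymphatics
                        "Hb": (1.0, 0.0, 0.0),      # red, blood
                        "HbO2": (1.0, 0.3, 0.0),
                        "PA": (1.0, 0.1, 0.1)}


def overlay(us: BScanImage, pa: BScanImage, threshold_db: float = -20.0,
            alpha: float = 0.7, pa_color: str | tuple = "PA") -> np.ndarray:
    """PA-over-US composite: grayscale US, colored PA where above threshold.

    Both images must share geometry.  The US image is rendered on its dB
    scale; PA pixels at or above ``threshold_db`` relative to the PA peak are
    alpha-blended in the species color (ICG green / Hb red convention).
    """
    if us.pixels.shape != pa.pixels.shape or \
            abs(us.pixel_size_mm - pa.pixel_size_mm) > 1e-9:
        raise ValueError("registration error: geometry mismatch")
    color = np.array(FIXED_SPECIES_COLORS[pa_color]) \
        if isinstance(pa_color, str) else np.asarray(pa_color, dtype=float)

    us_px = us.pixels.astype(float)
    if us.kind == "db":
        dr = us.dynamic_range_db
        gray = (us_px + dr) / dr
    else:
        m = np.abs(us_px).max()
        gray = np.abs(us_px) / m if m > 0 else np.abs(us_px)
    rgb = np.repeat(np.clip(gray, 0, 1)[..., None], 3, axis=2)

    pa_px = np.abs(pa.pixels.astype(float))
    if pa.kind == "db":
        # dB images are already referenced to their 0 dB peak
        pa_norm = pa.pixels.astype(float)
    else:
        peak = pa_px.max()
        with np.errstate(divide="ignore"):
            pa_norm = 20.0 * np.log10(pa_px / peak) if peak > 0 \
                else np.full_like(pa_px, -np.inf)
    hot = pa_norm >= threshold_db
    a = np.where(hot, alpha, 0.0)[..., None]
    return (1.0 - a) * rgb + a * color[None, None, :]
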