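"""File formats: HDF5 channel data, NIfTI volumes, TIFF images, YAML scenes.

The HDF5 channel-data container stores /traces (3-D), /meta (JSON-serialized
specs and provenance) and an /events table; volumes go to NIfTI with mm
spacings in the header; B-scans to 32-bit TIFF with a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import tifffile
import yaml

from .forward import ChannelData
from .phantom import (Background, DigitalPhantom, GridSpec, VesselSpec,
                      make_phantom)
from .recon import BScanImage
from .volume import Volume3D


# ---------------------------------------------------------------------------
# channel data (HDF5)

def save_channel_data(path: str | Path, items: list[ChannelData]) -> None:
    """Write an ordered acquisition stream to one HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["n_items"] = len(items)
        for i, cd in enumerate(items):
            g = f.create_group(f"item_{i:05d}")
            g.create_dataset("traces", data=cd.traces, compression="gzip")
            g.attrs["modality"] = cd.modality
            g.attrs["sampling_mhz"] = cd.sampling_mhz
            g.attrs["gain_db"] = cd.gain_db
            g.attrs["t0_s"] = cd.t0_s
            g.attrs["meta"] = json.dumps(cd.provenance, default=str)
            g.attrs["events"] = json.dumps(cd.events)


def load_channel_data(path: str | Path) -> list[ChannelData]:
    out = []
    with h5py.File(path, "r") as f:
        for i in range(int(f.attrs["n_items"])):
            g = f[f"item_{i:05d}"]
            out.append(ChannelData(
                traces=g["traces"][...],
                modality=str(g.attrs["modality"]),
                events=json.loads(g.attrs["events"]),
                sampling_mhz=float(g.attrs["sampling_mhz"]),
                gain_db=float(g.attrs["gain_db"]),
                t0_s=float(g.attrs["t0_s"]),
                provenance=json.loads(g.attrs["meta"])))
    return out


# ---------------------------------------------------------------------------
# volumes (NIfTI)

def save_volume_nifti(path: str | Path, vol: Volume3D) -> None:
    """Volume to NIfTI; voxel spacings (mm) in the affine."""
    affine = np.diag([vol.voxel_size_mm, vol.y_step_mm, vol.voxel_size_mm, 1.0])
    img = nib.Nifti1Image(np.transpose(vol.voxels, (2, 1, 0)).astype(np.float32),
                          affine)
    img.header["descrip"] = vol.channel.encode()[:79]
    nib.save(img, str(path))


def load_volume_nifti(path: str | Path) -> Volume3D:
    img = nib.load(str(path))
    data = np.transpose(np.asarray(img.dataobj, dtype=float), (2, 1, 0))
    zooms = img.header.get_zooms()
    return Volume3D(voxels=data, voxel_size_mm=float(zooms[0]),
                    y_step_mm=float(zooms[1]),
                    channel=img.header["descrip"].tobytes().decode(
                        errors="ignore").strip("\x00"))


def save_phantom_nifti(dirpath: str | Path, phantom: DigitalPhantom) -> None:
    """One NIfTI file per species grid plus a YAML scene description."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    aff = np.diag([phantom.grid.voxel_size_mm] * 3 + [1.0])
    for s, g in phantom.conc.items():
        nib.save(nib.Nifti1Image(g.astype(np.float32), aff),
                 str(dirpath / f"conc_{s}.nii.gz"))
    nib.save(nib.Nifti1Image(phantom.scatter_amp.astype(np.float32), aff),
             str(dirpath / "scatter_amp.nii.gz"))
    save_scene_yaml(dirpath / "scene.yaml", phantom)


# ---------------------------------------------------------------------------
# B-scans (TIFF + JSON sidecar)

def save_bscan_tiff(path: str | Path, img: BScanImage) -> None:
    path = Path(path)
    tifffile.imwrite(path, img.pixels.astype(np.float32))
    sidecar = {"extent_mm": list(img.extent_mm),
               "pixel_size_mm": img.pixel_size_mm,
               "modality": img.modality, "kind": img.kind,
               "wavelength_nm": img.wavelength_nm,
               "frame_index": img.frame_index,
               "dynamic_range_db": img.dynamic_range_db,
               "provenance": img.provenance}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2,
                                                    default=str))


def load_bscan_tiff(path: str | Path) -> BScanImage:
    path = Path(path)
    pixels = tifffile.imread(path).astype(float)
    side = json.loads(path.with_suffix(".json").read_text())
    return BScanImage(pixels=pixels, extent_mm=tuple(side["extent_mm"]),
                      pixel_size_mm=side["pixel_size_mm"],
                      modality=side["modality"], kind=side["kind"],
                      wavelength_nm=side["wavelength_nm"],
                      frame_index=side["frame_index"],
                      dynamic_range_db=side["dynamic_range_db"],
                      provenance=side.get("provenance", {}))


# ---------------------------------------------------------------------------
# scenes (YAML)

def save_scene_yaml(path: str | Path, phantom: DigitalPhantom) -> None:
    scene = {
        "grid": {"shape": list(phantom.grid.shape),
                 "voxel_size_mm": phantom.grid.voxel_size_mm},
        "background": {"mu_a_mm": phantom.background.mu_a_mm,
                       "mu_s_prime_mm": phantom.background.mu_s_prime_mm,
                       "scatter_density_per_mm3":
                           phantom.background.scatter_density_per_mm3,
                       "scatter_amp_sigma": phantom.background.scatter_amp_sigma},
        "sound_speed_mps": phantom.sound_speed_mps,
        "seed": phantom.seed,
        "vessels": [{"centerline": v.centerline.tolist(),
                     "radius_mm": v.radius_mm,
                     "species_mix": dict(v.species_mix),
                     "so2": v.so2, "arterial": v.arterial}
                    for v in phantom.vessels],
    }
    Path(path).write_text(yaml.safe_dump(scene, sort_keys=False))


def load_scene_yaml(path: str | Path) -> DigitalPhantom:
    scene = yaml.safe_load(Path(path).read_text())
    grid = GridSpec(shape=tuple(scene["grid"]["shape"]),
                    voxel_size_mm=scene["grid"]["voxel_size_mm"])
    bg = Background(**scene["background"])
    vessels = [VesselSpec(centerline=np.asarray(v["centerline"]),
                          radius_mm=v["radius_mm"],
                          species_mix=v["species_mix"], so2=v.get("so2"),
                          arterial=v.get("arterial", False))
               for v in scene["vessels"]]
    return make_phantom(vessels, grid, bg, seed=scene.get("seed", 0),
                        sound_speed_mps=scene.get("sound_speed_mps", 1540.0))
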