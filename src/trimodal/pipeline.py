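"""End-to-end orchestration: scenes, acquisition simulation, processing runs.

Ties the modules together: build a scene, simulate the acquisition sequence
(PA events per wavelength, each followed by steered US packets after the
programmed delay), reconstruct, compensate, unmix, and write artifacts with
a reproducibility manifest (config hash, seed, output hashes).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .forward import (AcquisitionSpec, BeamModel, ChannelData, TransducerSpec,
                      fluence_analytic, fluorescence_frame, pa_channel_data,
                      us_channel_data)
from .io import (load_channel_data, save_bscan_tiff, save_channel_data,
                 save_scene_yaml, load_scene_yaml)
from .phantom import (Background, DigitalPhantom, DynamicsSpec, GridSpec,
                      VesselSpec, absorption_map, blood_mix, make_phantom,
                      modulate_pulsatile)
from .recon import ImageGrid, das_pa, das_us, envelope, frame_sequencer
from .spectra import SpectraTable
from .spectral import SpectralStack, build_M, fluence_compensate, so2_map, unmix

IN_VITRO_WAVELENGTHS = (690.0, 720.0, 756.0, 796.0)
IN_VIVO_WAVELENGTHS = (690.0, 756.0, 796.0, 820.0, 866.0)

BLOOD_TOTAL_MOLAR = 2.3e-3      # whole-blood heme concentration
ICG_LYMPH_MOLAR = 1.0e-5        # in-vessel ICG after intradermal uptake


# ---------------------------------------------------------------------------
# canned scenes

def two_tube_scene(grid: GridSpec | None = None, depth_mm: float = 3.0,
                   so2: float = 0.95, seed: int = 0) -> DigitalPhantom:
    """Blood tube + ICG tube at 3 mm depth: the trimodal benchmark scene."""
    grid = grid or GridSpec((128, 1, 80), 0.15)
    y = 0.0
    ex = grid.extent_mm[0]
    blood = VesselSpec(
        centerline=np.array([[-ex / 4, y, depth_mm], [-ex / 4 + 1e-3, y, depth_mm]]),
        radius_mm=0.5, species_mix=blood_mix(BLOOD_TOTAL_MOLAR, so2))
    icg = VesselSpec(
        centerline=np.array([[ex / 4, y, depth_mm], [ex / 4 + 1e-3, y, depth_mm]]),
        radius_mm=0.5, species_mix={"ICG": ICG_LYMPH_MOLAR})
    return make_phantom([blood, icg], grid, Background(), seed=seed)


def lymphatic_toy_scene(grid: GridSpec | None = None,
                        seed: int = 0) -> DigitalPhantom:
    """Vein + lymphatic pair ~3 mm deep, as in small-animal lymphography."""
    grid = grid or GridSpec((128, 8, 80), 0.15)
    ex, ey, _ = grid.extent_mm
    vein = VesselSpec(
        centerline=np.array([[-ex / 5, -ey / 2 + 1.0, 3.0],
                             [-ex / 5, ey / 2 - 1.0, 3.2]]),
        radius_mm=0.45, species_mix=blood_mix(BLOOD_TOTAL_MOLAR, 0.7))
    lymph = VesselSpec(
        centerline=np.array([[ex / 5, -ey / 2 + 1.0, 3.0],
                             [ex / 5, ey / 2 - 1.0, 2.8]]),
        radius_mm=0.45, species_mix={"ICG": ICG_LYMPH_MOLAR})
    return make_phantom([vein, lymph], grid, Background(), seed=seed)


def pulsatile_arm_scene(grid: GridSpec | None = None, seed: int = 0
                        ) -> tuple[DigitalPhantom, DynamicsSpec]:
    """Forearm-like cross-section with an 84 bpm artery (200 frames @ 20 Hz)."""
    grid = grid or GridSpec((128, 1, 80), 0.15)
    ex = grid.extent_mm[0]
    artery = VesselSpec(
        centerline=np.array([[0.0, 0.0, 5.0], [1e-3, 0.0, 5.0]]),
        radius_mm=0.8, species_mix=blood_mix(BLOOD_TOTAL_MOLAR, 0.95),
        arterial=True)
    vein = VesselSpec(
        centerline=np.array([[-ex / 4, 0.0, 3.0], [-ex / 4 + 1e-3, 0.0, 3.0]]),
        radius_mm=0.6, species_mix=blood_mix(BLOOD_TOTAL_MOLAR, 0.7))
    phantom = make_phantom([artery, vein], grid, Background(), seed=seed)
    dyn = DynamicsSpec(heart_rate_bpm=84.0, modulation_depth=0.15,
                       frame_rate_hz=20.0, n_frames=200)
    return phantom, dyn


# ---------------------------------------------------------------------------
# acquisition simulation

def simulate_frame(phantom: DigitalPhantom, tx: TransducerSpec,
                   acq: AcquisitionSpec, beam: BeamModel | None = None,
                   spectra: SpectraTable | None = None,
                   slice_iy: int | None = None,
                   frame_t0_s: float = 0.0) -> list[ChannelData]:
    """One spectral cycle of the acquisition sequence.

    Per wavelength a PA receive event; the steered US packets follow the
    last PA event by the programmed PA->US delay, mirroring the hardware
    sequence timing recorded in the event metadata.
    """
    beam = beam or BeamModel("coaxial")
    spectra = spectra or SpectraTable.default()
    items: list[ChannelData] = []
    event_spacing_s = 1.0 / (acq.frame_rate_hz * max(len(acq.wavelengths_nm), 1))
    t = frame_t0_s
    for wl in acq.wavelengths_nm:
        mua = absorption_map(phantom, wl, spectra)
        phi = fluence_analytic(mua, phantom.mu_s_prime_background,
                               BeamModel(beam.kind, beam.fiber_diameter_mm,
                                         beam.divergence_full_angle_deg,
                                         wavelength_nm=wl), phantom.grid)
        pa = pa_channel_data(phantom, phi, tx, acq, wl, spectra,
                             slice_iy=slice_iy)
        pa.events[0]["t0_s"] = t
        items.append(pa)
        t += event_spacing_s
    t_us = items[-1].events[0]["t0_s"] + acq.pa_us_delay_us * 1e-6
    for ang in acq.steer_angles_deg:
        us = us_channel_data(phantom, tx, acq, ang, slice_iy=slice_iy)
        for ev in us.events:
            ev["t0_s"] = t_us
        items.append(us)
    return items


# ---------------------------------------------------------------------------
# pipeline config and runner

@dataclass
class PipelineConfig:
    """Validated configuration of an end-to-end run."""

    out_dir: str
    seed: int
    scene: str = "two_tube"                 # scene kind or path to scene.yaml
    species: tuple[str, ...] = ("Hb", "HbO2", "ICG")
    wavelengths_nm: tuple[float, ...] = IN_VITRO_WAVELENGTHS
    noise_rms: float = 0.0
    stages: tuple[str, ...] = ("simulate", "recon", "unmix", "metrics")
    pixel_size_mm: float = 0.15
    raw_path: str | None = None             # reuse an existing container

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("species", "wavelengths_nm", "stages"):
            if key in data:
                data[key] = tuple(data[key])
        cfg = cls(**data)
        if cfg.seed is None:
            raise ValueError("seed is mandatory")
        if cfg.scene not in ("two_tube", "lymphatic_rat_toy",
                             "pulsatile_arm_toy") and \
                not Path(cfg.scene).exists():
            raise FileNotFoundError(f"scene {cfg.scene!r} not found")
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _build_scene(cfg: PipelineConfig) -> DigitalPhantom:
    if cfg.scene == "two_tube":
        return two_tube_scene(seed=cfg.seed)
    if cfg.scene == "lymphatic_rat_toy":
        return lymphatic_toy_scene(seed=cfg.seed)
    if cfg.scene == "pulsatile_arm_toy":
        return pulsatile_arm_scene(seed=cfg.seed)[0]
    return load_scene_yaml(cfg.scene)


def run_pipeline(cfg: PipelineConfig, log=print) -> dict:
    """Execute simulate -> recon -> unmix -> metrics, writing a manifest.

    Each stage logs one line with wall time; any stage failure aborts with
    the stage name while keeping earlier partial outputs on disk.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tx = TransducerSpec()
    acq = AcquisitionSpec(wavelengths_nm=cfg.wavelengths_nm,
                          noise_rms=cfg.noise_rms, seed=cfg.seed)
    spectra = SpectraTable.default()
    manifest: dict = {"version": __version__, "seed": cfg.seed,
                      "config": asdict(cfg), "stages": {}, "outputs": {}}
    raw_path = Path(cfg.raw_path) if cfg.raw_path else out / "raw.h5"

    def _stage(name):
        return name in cfg.stages

    try:
        if _stage("simulate"):
            t0 = time.perf_counter()
            phantom = _build_scene(cfg)
            save_scene_yaml(out / "scene.yaml", phantom)
            items = simulate_frame(phantom, tx, acq, spectra=spectra)
            save_channel_data(raw_path, items)
            fl = fluorescence_frame(phantom)
            np.save(out / "fl_frame.npy", fl)
            manifest["stages"]["simulate"] = {
                "wall_s": round(time.perf_counter() - t0, 3),
                "n_events": len(items)}
            log(f"simulate: {len(items)} events -> {raw_path} "
                f"[{manifest['stages']['simulate']['wall_s']} s]")

        frames_dir = out / "frames"
        if _stage("recon"):
            t0 = time.perf_counter()
            items = load_channel_data(raw_path)
            frames_dir.mkdir(exist_ok=True)
            grid = ImageGrid(x_span_mm=19.2, z_span_mm=12.0,
                             pixel_size_mm=cfg.pixel_size_mm)
            n_img = 0
            for bundle in frame_sequencer(items):
                for wl, cd in bundle.pa.items():
                    img = envelope(das_pa(cd, tx, grid))
                    img.frame_index = bundle.frame_index
                    save_bscan_tiff(frames_dir /
                                    f"f{bundle.frame_index:03d}_pa{int(wl)}.tif",
                                    img)
                    n_img += 1
                us_img = envelope(das_us(bundle.us_packets, tx, grid))
                us_img.frame_index = bundle.frame_index
                save_bscan_tiff(frames_dir / f"f{bundle.frame_index:03d}_us.tif",
                                us_img)
                n_img += 1
            manifest["stages"]["recon"] = {
                "wall_s": round(time.perf_counter() - t0, 3), "n_images": n_img}
            log(f"recon: {n_img} images -> {frames_dir} "
                f"[{manifest['stages']['recon']['wall_s']} s]")

        if _stage("unmix"):
            t0 = time.perf_counter()
            import tifffile
            pa_paths = sorted(frames_dir.glob("f000_pa*.tif"))
            wls = sorted(float(p.stem.split("pa")[1]) for p in pa_paths)
            images = np.stack([
                tifffile.imread(frames_dir / f"f000_pa{int(w)}.tif")
                for w in wls])
            stack = SpectralStack(images=images, wavelengths_nm=np.array(wls),
                                  pixel_size_mm=cfg.pixel_size_mm)
            stack = fluence_compensate(stack)
            # unnormalized rows keep Hb/HbO2 ratios physical for sO2 mapping
            M = build_M(spectra, wls, list(cfg.species),
                        normalize=not ({"Hb", "HbO2"} <= set(cfg.species)))
            maps = unmix(stack, M, species=list(cfg.species))
            if "Hb" in maps.conc and "HbO2" in maps.conc:
                maps = so2_map(maps)
            for s, img in maps.conc.items():
                tifffile.imwrite(out / f"unmixed_{s}.tif",
                                 img.astype(np.float32))
            if maps.so2 is not None:
                tifffile.imwrite(out / "so2.tif",
                                 maps.so2.filled(np.nan).astype(np.float32))
            manifest["stages"]["unmix"] = {
                "wall_s": round(time.perf_counter() - t0, 3),
                "threshold_used": maps.threshold_used}
            log(f"unmix: {len(maps.conc)} species maps -> {out} "
                f"[{manifest['stages']['unmix']['wall_s']} s]")

        if _stage("metrics"):
            t0 = time.perf_counter()
            import tifffile
            metrics = {}
            icg_path = out / "unmixed_ICG.tif"
            if icg_path.exists():
                icg = tifffile.imread(icg_path)
                metrics["icg_peak"] = float(np.max(icg))
                metrics["icg_total"] = float(np.sum(np.clip(icg, 0, None)))
            (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
            manifest["stages"]["metrics"] = {
                "wall_s": round(time.perf_counter() - t0, 3)}
            log(f"metrics -> {out / 'metrics.json'} "
                f"[{manifest['stages']['metrics']['wall_s']} s]")
    except Exception as err:  # abort with the failing stage name
        done = list(manifest["stages"])
        stage = (set(cfg.stages) - set(done))
        raise RuntimeError(
            f"pipeline stage {sorted(stage)[0] if stage else '?'} failed: {err}"
        ) from err

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][str(p.relative_to(out))] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return manifest


# ---------------------------------------------------------------------------
# fixtures

FIXTURE_KINDS = ("two_tube", "lymphatic_rat_toy", "pulsatile_arm_toy")


def make_fixtures(kind: str, seed: int, out_dir: str | Path) -> dict:
    """Write a scene YAML + raw HDF5 + checksums for a canned scene.

    ``pulsatile_arm_toy`` records the 200-frame 20 Hz ROI series of the
    84 bpm artery instead of full channel data for every frame.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; have {FIXTURE_KINDS}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tx = TransducerSpec()
    spectra = SpectraTable.default()
    if kind == "two_tube":
        phantom = two_tube_scene(seed=seed)
        acq = AcquisitionSpec(wavelengths_nm=IN_VITRO_WAVELENGTHS, seed=seed)
        items = simulate_frame(phantom, tx, acq, spectra=spectra)
        save_channel_data(out / "raw.h5", items)
    elif kind == "lymphatic_rat_toy":
        phantom = lymphatic_toy_scene(seed=seed)
        acq = AcquisitionSpec(wavelengths_nm=IN_VIVO_WAVELENGTHS, seed=seed)
        items = simulate_frame(phantom, tx, acq, spectra=spectra)
        save_channel_data(out / "raw.h5", items)
    else:
        phantom, dyn = pulsatile_arm_scene(seed=seed)
        series = np.array([
            modulate_pulsatile(phantom, dyn, i).conc["HbO2"].sum()
            for i in range(dyn.n_frames)])
        np.savetxt(out / "roi_series.csv", series, header="roi_mean",
                   comments="")
    save_scene_yaml(out / "scene.yaml", phantom)
    checksums = {p.name: _sha256(p) for p in sorted(out.iterdir())
                 if p.is_file() and p.name != "checksums.json"}
    (out / "checksums.json").write_text(json.dumps(checksums, indent=2))
    return checksums
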