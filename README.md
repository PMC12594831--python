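# trimodal

Simulation and processing pipeline for trimodal **ultrasound /
photoacoustic / fluorescence** imaging with a 64-element transparent
linear-array probe (300 µm pitch, 7 MHz, 45% bandwidth). A transparent
transducer lets the laser pass coaxially through the acoustic aperture, so a
single handheld device can image anatomy (US), optical absorbers such as
hemoglobin and indocyanine green (PA), and ICG fluorescence en face (FL) —
the combination used to map vasculature, oxygen saturation and lymphatics,
e.g. for lymphaticovenous-anastomosis surgical planning.

The package is aimed at people building or validating such processing
chains: it generates physically structured synthetic raw data, runs the full
reconstruction/unmixing stack on it, and measures the standard transducer
and image-quality figures of merit.

## What is implemented

- **`phantom`** — voxel scenes: capsule vessels/lymphatics with exact
  Hb/HbO2/ICG composition, speckle scatterers, pulsatile arteries driven by
  a zero-mean raised-cosine pulse train (e.g. 84 bpm → 1.4 Hz fundamental
  with harmonics).
- **`forward`** — raw channel data: PA point-source superposition with
  band-limited pulses (p0 = Γ·µa·Φ), steered line-beam US with two-way
  delays, en-face FL projection with round-trip attenuation, analytic
  diffusion fluence Φ(z) ∝ exp(−µ_eff·z), µ_eff = √(3µa(µa+µs′)).
- **`recon`** — delay-and-sum beamforming (one-way PA, two-way US with
  coherent compounding of the 0°/−10°/+10° packets), envelope detection,
  log compression, spectral-cycle frame sequencing.
- **`spectral`** — depth-wise fluence compensation, pseudo-inverse unmixing
  `C = PA·Mᵀ·(M·Mᵀ)⁻¹`, and sO2 = m_HbO2/(m_HbO2+m_Hb) with masking.
- **`volume`** — mosaic stitching of overlapping lanes with linear
  feathering, MAP and depth-encoded projections, PA/US overlays.
- **`mcfluence`** — numba voxel Monte Carlo (Henyey–Greenstein, Russian
  roulette, escaping boundaries) for the coaxial-vs-oblique illumination
  comparison.
- **`metrology`** — k_eff from impedance resonances, pulse-echo
  center-frequency/bandwidth/SNR, crosstalk in dB, FWHM, CNR, pulsation
  spectra, fold change.
- **`cli`** — `trimodal simulate | recon | unmix | volume | mcfluence |
  metrics | pipeline | fixtures`.

Chromophore spectra (Hb, HbO2, ICG-in-plasma; 660–900 nm) ship as a CSV
with provenance in its header. File formats: HDF5 channel data, NIfTI
volumes, TIFF B-scans with JSON sidecars, YAML scenes/configs.

## Worked example

Simulate the two-tube benchmark scene (one tube of blood, one of ICG, both
3 mm deep), reconstruct one spectral cycle, compensate, unmix:

```python
import numpy as np
from trimodal import (TransducerSpec, AcquisitionSpec, SpectraTable,
                      das_pa, envelope, build_M, fluence_compensate,
                      unmix, keff_from_frequencies)
from trimodal.pipeline import two_tube_scene, simulate_frame
from trimodal.recon import ImageGrid, frame_sequencer
from trimodal.spectral import SpectralStack

tx = TransducerSpec()                     # 64 el, 0.3 mm pitch, 7 MHz, 45% BW
acq = AcquisitionSpec(wavelengths_nm=(690.0, 720.0, 756.0, 796.0), seed=0)
scene = two_tube_scene(seed=0)            # blood + ICG tubes, 3 mm deep
stream = simulate_frame(scene, tx, acq)   # 4 PA events + 3 steered US packets
bundle = next(frame_sequencer(stream))

grid = ImageGrid(x_span_mm=19.2, z_span_mm=12.0, pixel_size_mm=0.15)
images = np.stack([envelope(das_pa(bundle.pa[wl], tx, grid)).pixels
                   for wl in acq.wavelengths_nm])
stack = fluence_compensate(SpectralStack(images, np.array(acq.wavelengths_nm),
                                         pixel_size_mm=0.15))
M = build_M(SpectraTable.default(), acq.wavelengths_nm, ["Hb", "HbO2", "ICG"])
maps = unmix(stack, M, species=["Hb", "HbO2", "ICG"])

X, Z = np.meshgrid(grid.x_mm, grid.z_mm, indexing="xy")
blood_roi = (X + 4.8) ** 2 + (Z - 3.0) ** 2 <= 0.35 ** 2
icg_roi = (X - 4.8) ** 2 + (Z - 3.0) ** 2 <= 0.35 ** 2
peak = maps.conc["ICG"].max()
for s in ("ICG", "HbO2", "Hb"):
    print(f"{s:5s} map — ICG-tube ROI: {maps.conc[s][icg_roi].mean()/peak:6.3f}"
          f"   blood-tube ROI: {maps.conc[s][blood_roi].mean()/peak:6.3f}")
print(f"k_eff from f_r = 6.53 MHz, f_a = 7.54 MHz: "
      f"{keff_from_frequencies(6.53, 7.54):.2f}")
```

prints

```
ICG   map — ICG-tube ROI:  0.136   blood-tube ROI:  0.002
HbO2  map — ICG-tube ROI: -0.008   blood-tube ROI:  0.108
Hb    map — ICG-tube ROI:  0.002   blood-tube ROI:  0.018
k_eff from f_r = 6.53 MHz, f_a = 7.54 MHz: 0.50
```

Reading the numbers: the unmixed ICG map lights up only inside the ICG tube
(0.136 vs 0.002 — a ~60× isolation of the dye from blood), the HbO2 map
lights up only inside the blood tube, and the small negative HbO2 value in
the ICG tube is the unconstrained least-squares residual that the pipeline
deliberately keeps as a diagnostic. The last line evaluates the
electromechanical-coupling relation k_eff = √(1 − (f_r/f_a)²) at a measured
resonance/anti-resonance pair, giving 0.50.

`docs/methods.md` describes every model, default and limitation in detail.

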