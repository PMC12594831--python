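# Methods

This note documents the models behind `trimodal`, the assumptions they make,
the parameters that matter, and the numerical choices that were genuinely
open. It is written for someone who wants to know what the simulations do and
do not capture before trusting a number that comes out of them.

## System being modeled

The package emulates the computational chain of a handheld trimodal probe
built around a 64-element transparent linear ultrasound array (300 µm pitch,
7 MHz center frequency, 45% fractional bandwidth). The transparency permits
coaxial optical illumination through the array, so one device acquires:

- **US**: three packets of 7 MHz line-beam transmissions steered at
  0°, −10°, +10°, 64 lines per packet, compounded into one B-scan;
- **PA**: passive reception of laser-induced acoustic waves, one receive
  event per excitation wavelength (in-vitro cycle 690/720/756/796 nm,
  in-vivo cycle 690/756/796/820/866 nm), each followed 100 µs later by the
  US events; receive gains 54 dB (PA) and 39 dB (US);
- **FL**: an en-face NIR camera view of ICG fluorescence (800–900 nm band).

Elevational stepping (0.5 mm) turns B-scans into volumes; overlapping lanes
are mosaicked into a wider synthetic aperture.

## Digital phantoms (`phantom`)

Scenes are voxel grids (x lateral, y elevational, z depth, z = 0 at the
transducer face, mm units, half-open voxel extents) holding per-species
chromophore concentration (Hb, HbO2, ICG), acoustic scatterer amplitude, and
optical background (µa, µs′). Vessels are capsules around polyline
centerlines — a voxel belongs to a vessel when its center is within the
radius of the centerline, which adds hemispherical end caps; volume oracles
must therefore use the capsule volume. For blood, the Hb/HbO2 split is tied
to sO2 exactly. Speckle follows the fully-developed model: uniform random
sub-voxel scatterer positions with Gaussian amplitudes (default
2 scatterers/mm³), deterministic per seed.

Pulsatility scales arterial radius and concentration by
`1 + m·s(f0 t)` with `s` a zero-mean raised-cosine systolic pulse train
(duty 0.35 of the beat). A pulse train rather than a sinusoid was chosen so
the intensity spectrum carries the harmonic stack seen in arterial
pulsation; zero mean keeps the period-averaged cross-section within
`m²·var(s)` (< 1%) of the static one. A Nyquist guard rejects heart rates
above half the frame rate.

Default concentrations: whole blood 2.3 mM heme; lymphatic ICG 10 µM. The
in-vessel ICG level after intradermal uptake is not a measured quantity —
10 µM sits in the range where an ICG tube outshines a blood tube at 756 nm
while staying far below self-quenching, which reproduces the qualitative
contrast ordering of the two-tube benchmark.

## Chromophore spectra (`spectra`, `data/chromophores.csv`)

Molar extinction (cm⁻¹ M⁻¹) for Hb, HbO2 (per heme) and ICG bound to plasma
proteins, 660–900 nm, compiled approximately from the standard literature
tabulations and treated as external constants. Hb and HbO2 cross within 1%
at 796 nm (isosbestic); ICG peaks near 800 nm. Absorption converts as
µa[mm⁻¹] = ln(10)·ε·C/10. Queries outside the tabulated range raise — no
extrapolation.

## Forward models (`forward`)

**Analytic fluence** (fast stand-in for Monte Carlo when simulating channel
data): broad-beam diffusion decay `exp(−µ_eff·z_eff)` with
`µ_eff = sqrt(3 µa (µa+µs′))` from depth-averaged coefficients, path length
along the incidence direction, and a top-hat-with-Gaussian-edge footprint
that diverges with depth. Valid only as a smooth illumination prior; it has
no scattering buildup near the surface and no lateral diffusion.

**PA channel data**: every absorbing voxel radiates
`p0 = Γ·µa·Φ` (Γ fixed at 1 — it never appears in the acquisition chain as a
separate measurable) as a Gaussian-enveloped tone at the center frequency,
with the envelope σ set so the −6 dB two-sided spectral width equals the
fractional bandwidth. Delay r/c at c = 1540 m/s, amplitude p0/r, hard ±45°
element acceptance angle, additive white Gaussian noise (pre-gain), then the
receive gain 10^(dB/20). The elevational dimension is collapsed per slice
(2.5-D), matching a stepped B-scan acquisition.

**US channel data**: the transmit wavefront of each line is modeled as
spherical from the line-origin element, laterally confined by a Gaussian
(σ = 0.4 mm) around the steered line axis; receive is per element with the
same directivity rule, two-way 1/r spreading. The spherical-transmit choice
keeps arrival times reciprocal under exchange of transmit/receive roles and
lets a single delay model serve forward and reconstruction; its cost is
that steering enters only through the confinement weight, not the transmit
delay. No full-wave propagation, nonlinearity, or frequency-dependent
attenuation.

**Fluorescence**: a depth-weighted vertical projection
`Σ_z ICG·exp(−2·atten·z)` (round-trip attenuation, default 0.5 mm⁻¹). With
a 10⁻³ relative camera noise floor and a 6 dB detection margin this puts
the maximum detectable tube depth at ≈ 6.2 mm. No lens model.

## Reconstruction (`recon`)

Delay-and-sum with linear interpolation in time, dynamic receive aperture of
F-number 1 and Hann apodization by default (sidelobe control; the hardware
vendor's apodization is unknown). PA uses one-way delays; US uses the
two-way line model above, beamforming each line over pixels within 2.5σ of
its axis and compounding the three steered packets coherently (incoherent
compounding is available behind a flag — whether the commercial platform
compounds coherently is unknown; coherent is the standard choice for
resolution). Gains are normalized away using the recorded dB values, so
simulation gain and reconstruction are inverse operations to float
precision. An optional spreading weight (r/z) undoes the spherical 1/r taper
across the aperture; it is used by the resolution benchmark, whose λ·F#
reference assumes a uniformly weighted aperture, and is off by default.
Display: analytic-signal envelope along depth, 20·log10 normalization to the
image peak, floors at −40 dB (US) and −30 dB (PA) by default. Default pixel
grid 0.1 mm over the 40 × 20 mm field of view.

The frame sequencer groups an ordered event stream into spectral-cycle
bundles (one PA image per wavelength + one compounded US image), checking
the 100 µs PA→US delay when event times are present and failing loudly on
incomplete cycles.

## Spectral processing (`spectral`)

**Fluence compensation**: per wavelength, the background level of each depth
row is its 20th-percentile intensity over non-object pixels; a single
exponential is fit (log-linear least squares, decay clamped non-negative)
and each row is divided by the fitted curve normalized to 1 at the surface.
The estimator behind "background level at each depth" is not prescribed
anywhere; percentile + single exponential is this package's documented
choice and both knobs are exposed. Rows with fewer than 8 background pixels
fall back to the global fit with a warning.

**Unmixing**: per pixel, `C = PA·Mᵀ·(M·Mᵀ)⁻¹` — unconstrained least
squares via the explicit pseudo-inverse. Negative concentrations are kept
in stored maps (they are diagnostic of model mismatch) and clamped only
when forming sO2 or display. `build_M` samples each species spectrum at the
acquisition wavelengths and by default normalizes rows to unit maximum,
which puts all species maps on comparable display scales. **For sO2 the
normalization must be skipped** (`normalize=False`): per-row scaling
multiplies each recovered species by its row maximum, which biases the
HbO2 fraction (for a true sO2 of 0.90 the row-normalized estimate is
exactly 0.9·1100/(0.9·1100 + 0.1·2052) = 0.83 with the shipped spectra).
The sO2-bearing pipelines therefore unmix with raw extinction rows, and
`sO2 = m_HbO2/(m_HbO2 + m_Hb)` with negatives clamped to zero before the
ratio, masked where total hemoglobin falls below 5% of the stack's
99th-percentile amplitude.

## Volumes and projections (`volume`)

Lanes are registered by stage coordinates alone (a motorized stage is
trusted; no image registration). Overlaps are blended by linear feathering
over the full overlap width with weights normalized to sum to one, so
stitching two lanes cut from one volume reproduces it exactly. MAP is the
per-column maximum of |voxels|; depth encoding maps the argmax depth
linearly over 0–10 mm through viridis (perceptually uniform, hue strictly
monotone in depth), scales color by normalized MAP amplitude and makes
empty columns transparent. Overlays render US in grayscale and alpha-blend
PA or unmixed species (ICG green, Hb red) above a dB threshold referenced
to the PA peak.

## Monte Carlo fluence (`mcfluence`)

Standard weighted-photon voxel MC in cm units: exponential step sampling by
the local µt, absorption deposit `w·µa/µt` at the arrival voxel,
Henyey–Greenstein scattering, Russian roulette below weight 10⁻⁴ with
survival probability 0.1. All six volume boundaries terminate photons
(escape). The beam is x-y factorizable: independent uniform launch offsets
within the fiber radius (1 mm diameter) and independent uniform tilts
within the 40° full divergence per axis, rotated for oblique incidence
(45°, 4 mm offset) — coaxial is normal incidence on the imaging axis.
Output is deposited weight / (µa · voxel volume · n_photons); per-voxel
standard errors come from deposition counts.

Numerical choices: steps are not split at voxel boundaries (exact for the
homogeneous media used throughout; approximate for heterogeneous ones);
the refractive boundary is matched (no Fresnel term — the reference
configuration does not state one); roulette preserves energy only in
expectation, so the conservation ledger tracks the roulette net
(killed − boosted weight) and `energy_balance_error` includes it, which
reduces to the plain absorbed + escaped = launched identity whenever
roulette never fires (vacuum and absorption-only scenarios).

Default desk scale is 10⁵ photons (the reference setting of 10⁷ is an
opt-in long run); the grid defaults to 5 × 5 × 1.5 cm³ at 0.05 cm voxels
and the benchmark comparison uses a 3 × 3 × 1.5 cm³ crop for speed. At 10⁵
photons the coaxial-vs-oblique comparison is decisive down to ≈ 1.3 cm; in
the deepest voxels both beams are fully diffused, the on-axis ratio
approaches 1 and single-voxel MC noise (~10%) can flip the strict per-depth
comparison — that is estimator noise, not a physics reversal, and the
standard errors reported alongside the curves quantify it. Tissue optical
coefficients for the comparison default to generic soft tissue
(µa = 0.2 cm⁻¹, µs′ = 10 cm⁻¹, g = 0.9) and are config-exposed.

## Metrology (`metrology`)

- `k_eff`: impedance-magnitude minimum (resonance) and subsequent maximum
  (anti-resonance) with parabolic sub-sample refinement, then the standard
  resonance relation `sqrt(1 − (f_r/f_a)²)`; validated by reproducing 0.50
  from the resonance pair 6.53/7.54 MHz.
- Pulse-echo: Hann-windowed FFT, −6 dB crossings by linear interpolation,
  center = midpoint of the crossings; SNR = peak amplitude over pre-echo
  RMS with a 1 µs guard. For a pure tone the bandwidth collapses to the
  spectral-resolution floor rather than erroring.
- Crosstalk: band-limited (1–9 MHz default) RMS of a neighbor over the
  driven element in dB, with a pass/fail flag against −30 dB.
- FWHM: linear-interpolated half-maximum crossings; boundary peaks are
  rejected as undefined.
- CNR: |µ_t − µ_b| / sqrt(σ_t² + σ_b²) on linear-envelope pixels (pooled
  denominator; a background-only denominator is available behind a flag —
  the estimator used for the published hardware values is unstated, so
  neither variant is treated as ground truth).
- Pulsation: linear detrend, Hann window, FFT; fundamental = largest
  non-DC peak with parabolic refinement; harmonics = spectral peaks within
  1.5 bins of integer multiples. Constant input returns a flagged no-peak
  result rather than raising.
- Fold change: post/pre ROI mean ratio.

## Problem sizes used by the benchmark suite

The acceptance computations run the full chains at desk scale, chosen so
each quantity is measured well inside its numerical noise floor: unmixing
exactness on 1000 random triplets; sO2 recovery on a 14.4 × 9.6 mm
single-slice artery scene at 0.15 mm pixels, five wavelengths, 20 dB
channel SNR, 10 seeded replicates; beamformer oracle on a 16-element array
with 3 point targets; Monte Carlo at 10⁵ photons; pulsation on
200 frames at 20 Hz; mosaics on a 12 × 3 × 4 mm smooth random volume;
resolution on the full 64-element aperture at the 20 mm focus.

## Known limitations

- Acoustics are linear, lossless, constant-speed (1540 m/s); no
  heterogeneous speed, attenuation dispersion, or full-wave effects — point
  spreads are diffraction-faithful but real tissue aberration is absent.
- The analytic fluence prior has no near-surface scattering buildup, so
  absolute PA amplitudes near z = 0 are optimistic.
- The US transmit model synthesizes focusing from spherical line sources;
  steered-packet compounding therefore improves speckle but the transmit
  aperture itself is one element wide.
- Synthetic scenes have piecewise-constant chromophores inside capsular
  vessels; passing the recovery tests demonstrates correctness of the
  processing chain, not robustness to real-tissue spectral coloring,
  motion, or out-of-plane signal.
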