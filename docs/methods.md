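# Methods

This note records the models implemented in `spiralpam`, their assumptions,
the defaults that matter, and the choices made where the design was open.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Cantilever mechanics and spiral kinematics

The fiber scanner is an Euler–Bernoulli cantilever of circular cross-section.
Its first flexural resonance is ω = β √(E/ρ)·R/L² with β = (k₁L)²/2 and
k₁L = 1.87510407 the first root of cos(kL)·cosh(kL) = −1; the factor 1/2 is
the radius of gyration of a solid circular section (√(EI/ρA) = (R/2)·√(E/ρ)).
Defaults describe a stripped single-mode silica fiber: E = 73 GPa,
ρ = 2200 kg/m³, R = 62.5 µm, L = 18 mm. The test suite checks the closed form
against a finite-difference beam eigensolve to 0.5%. Real scanners resonate a
few percent above this estimate (clamping compliance, coating), which is why
the operating frequency is a protocol parameter rather than derived.

Two trajectory models are provided:

* **kinematic** — the ideal spiral: radius follows the commanded linear ramp
  (0 → `max_radius` over `imaging_duration`), shrinks linearly to
  `brake_end_fraction·max_radius` during braking, and decays exponentially
  with time constant `decay_time_constant` (default `decay_duration/3`, so
  the residual is < 5% at cycle end) while always rotating at the scan
  frequency. Axis convention: x = a·sin, y = a·cos (y leads by a quarter
  period; counter-clockwise), origin at the rest position.
* **dynamic** — each axis integrates u'' + (ω₀/Q)u' + ω₀²u = ω₀²·d(t) with
  ω₀ from the beam formula and Q = π·f·`decay_time_constant` (this ties the
  only observable — ring-down — to the oscillator), then rescales so the
  steady imaging radius equals `max_radius`. A resonant oscillator tracks a
  ramp with a first-order lag of ≈ `decay_time_constant`; at high Q the
  dynamic radius therefore trails the kinematic ramp. The model-agreement
  test uses a short decay constant (0.5 ms against a 0.5 s ramp) where the
  lag is within the 2% band; with the full-cycle defaults the lag is a real,
  physical effect, not an integration artifact.

The braking drive profile and measured decay constant of the hardware are not
published; both are exposed as protocol parameters (`brake_end_fraction`,
`decay_time_constant`) with the defaults above.

Trajectories default to 500 kHz sampling — equal to the maximum laser PRF, so
trigger-position lookup is interpolation between neighboring samples and
never extrapolation.

## Trigger scheduling and density maps

The reference schedule steps the PRF through 20 kHz (0.05–0.1 s), 100 kHz
(0.1–0.2 s), 200 kHz (0.2–0.3 s), 250 kHz (0.3–0.4 s) and 500 kHz (0.4–1 s);
the laser is off before 50 ms and outside the imaging phase. Within a step,
pulses are spaced 1/PRF from the step start; the per-step count is
floor(duration·PRF + 10⁻⁹) — the epsilon keeps exact-integer products (e.g.
0.05 s × 20 kHz = 1000) from losing a pulse to binary rounding. The
reference schedule fires exactly 356,000 pulses.

One pixel-assignment routine (`spiralpam.gridding.position_to_pixel`) is
shared by the density map and the reconstruction: pixel center 0 at −FOV/2,
center `grid−1` at +FOV/2 (pitch FOV/(grid−1)), continuous indices rounded
half-away-from-zero. "Visited" pixels are found by resampling the beam path
at 5 MHz inside every laser-on interval, so consecutive path samples move
well under one pixel.

Simulating the reference protocol (333 Hz, linear ramp to 1.3 mm, 512×512
over 2.6 mm) yields a near-uniform density: ~99.4% of beam-visited pixels
receive 1–5 shots. The residuals are structural, not numerical: in the
20 kHz ring the pulses-per-turn ratio PRF/f = 60.06 is nearly integer, so
pulse angles advance only 0.36°/turn while the spiral pitch (3.9 µm/turn)
carries the beam off a pixel within ~1.3 turns, stranding unilluminated gaps
between pulse angles; and pixels at the radius where one PRF step hands over
to the next collect shots from both rings (up to 6 at the 250→500 kHz
boundary). Both effects are robust to the binning convention and tie-break.
The same mechanism, driven harder, is what the frequency sweep shows as
aliasing: when PRF/f is an integer the shot pattern locks onto fixed spokes
and the fill factor drops.

## KLM transducer model

The piezo plate is the standard KLM equivalent circuit: an acoustic
transmission line (impedance Z_c = ρvA, phase θ = ωd/v) tapped at its
midpoint through an ideal transformer, with electrical elements

* C₀ = ε^S ε₀ A/d,
* series reactance X₁ = k_t² sin θ / (θ ω C₀),
* turns ratio φ = k_t √(π/(ω₀ C₀ Z_c)) · sin(θ/2)/(θ/2), ω₀ = πv/d.

These constants were fixed by requiring the circuit to reproduce the Mason
closed-form input impedance for arbitrary face loads (the two circuits are
mathematically equivalent); the test suite verifies the full transfer
function against an independent Mason three-port impedance-matrix solve
(≤1% peak location, ≤3% normalized shape on random plates).

Matching layers are lossless transmission-line two-ports (a per-layer
attenuation hook in dB/MHz/cm exists, off by default, since no loss values
are published). Transmit transfer H_t(f) is the force delivered to the water
load per source volt behind 50 Ω. With fixed terminations the receive
transfer is exactly proportional — H_r = (2R_s/Z_F)·H_t, by reciprocity with
the radiation condition F − Z_F·u = 2F_inc — so the two-way spectrum is
H_t·H_r and its shape is H_t². The time-domain pulse echo is the inverse
real FFT on the default 0–150 MHz, 4096-point grid (zero-phase reference at
the grid origin).

**Backing.** The nominal 1 mm optical-epoxy backing is modeled as a
semi-infinite epoxy load. A lossless finite line terminated by air would
imprint a comb of backing resonances spaced v/2d ≈ 1.3 MHz that real epoxy —
tens of round-trip wavelengths at 33 MHz — attenuates away; terminating into
the backing impedance is the conventional design-simulation treatment. A
finite-thickness backing remains available in config.

**Material constants.** None are published for the device, so the package
ships a literature-class table, fully overridable in config: LNO 36°-rotated
Y-cut (v = 7340 m/s, ρ = 4640 kg/m³, k_t = 0.49, ε^S/ε₀ = 39), EPO-TEK
301-class epoxy (2650 m/s, 1150 kg/m³, 3.05 MRayl), and a silica-epoxy 0-3
composite at 4200 m/s, 2100 kg/m³ (8.8 MRayl). The composite default sits at
the DeSilets two-layer matching rule Z₁ = (Z_p⁴Z_w³)^(1/7) ≈ 8.9 MRayl for
LNO into water and is quarter-wave-consistent with the 30 µm first matching
layer at the design center frequency. Band metrics are sensitive to these
constants at roughly the ±10% level that motivates the acceptance tolerance.

−6 dB band metrics use the outermost crossings of (peak − 6 dB) around the
global maximum, located by linear interpolation; center frequency is the
crossing midpoint and fractional bandwidth their spread over it.

## Phantoms and the forward model

Vessel phantoms are biased random walks: roots start on one lateral edge,
headings receive Gaussian angular perturbations (`tortuosity`, default
0.25 rad/step with 2-voxel steps), depth wanders inside `depth_band`, and
side branches spawn with `branching_prob` at 0.6× the parent diameter.
Segments are rasterized as filled cylinders (absorption 1 inside, 0
outside); ground-truth centerlines and diameters ride along in `meta`.
Defaults (4 roots, 30–150 µm diameters) put vessels on both sides of the
100 µm macro/micro boundary. Edge, grid and point targets are deterministic
analytic patterns. What these phantoms emulate is absorption geometry only —
no optical fluence decay, scattering, or acoustic heterogeneity — so passing
tests demonstrate correctness of the computational chain, not in-tissue
image fidelity.

The forward model is single-scatter and ray-like: the beam deposits a
lateral Gaussian (σ = `focal_spot_sigma`, depth-independent — no defocus
model), the initial pressure at depth z arrives after a **one-way** flight
t = z/c (photoacoustic reception; note the transducer characterization above
is two-way), lands on the nearest digitizer sample (250 MHz default), and is
convolved with the transducer impulse whose index 0 is its time reference.
Receive sensitivity is flat across the FOV. Noise is white Gaussian, seeded;
`acquire` consumes one generator in fire order, so results are bit-reproducible.

## Reconstruction

Three-case assignment: single-sample pixels copy the trace; multi-sample
pixels average element-wise; empty pixels inside the FOV disc take an
inverse-distance-weighted sum of the nearest directly-hit pixels' whole
traces (defaults k = 4, power = 1; weights identical at every depth sample,
i.e. interpolation acts trace-wise — whether the original system
interpolated traces or projected values is unrecorded, and trace-wise is the
information-preserving choice). Pixels outside the disc stay zero. The
rounding tie-break (half away from zero) is documented and tested; the
position-sensor calibration of the hardware is replaced by the exact affine
map, since the simulator knows true positions.

Envelopes are |analytic signal| (Hilbert transform); MAP images are the
per-pixel envelope maximum along depth; depth encoding is the argmax index
with pixels under 5% of the global peak marked background.

## Quantification

* Lateral resolution: the ROI's rows are averaged into one profile, fitted to
  offset + (amplitude/2)(1 + erf((x−x₀)/σ√2)); FWHM = 2√(2 ln 2)·σ. Fits with
  relative RMSE > 0.15 raise instead of returning.
* Axial resolution: Gaussian fit to the envelope about its peak (window:
  contiguous samples ≥ 10% of peak), temporal FWHM × one-way c.
* SNR = 20·log₁₀(peak in signal ROI / std in noise ROI).
* Morphometry: VAD = area/total; skeleton by topological thinning, length
  from 4-neighbor steps (1) and diagonal steps (√2), with diagonals that
  merely shortcut an existing L-path not double-counted; VSD = length/total;
  VDI = area/length (so VDI·VSD = VAD identically); VCI = P²/(4πA) with the
  perimeter from the 4-direction Crofton estimator — chosen over
  boundary-pixel counts and marching-squares polygons because VCI is
  quadratic in P and those run 5–40% long on a disc, while Crofton is within
  ~0.5%.
* Macro/micro split at 100 µm local diameter: 2× the Euclidean distance
  transform on the skeleton, propagated to each vessel pixel via its nearest
  skeleton point.
* Time series: per-frame mask density (Otsu by default; a fixed threshold is
  available for reproducibility) and mean in-mask amplitude in dB
  (20·log₁₀ amplitude convention) relative to a baseline frame.

## Orchestration and determinism

`run_pipeline` resolves stage dependencies
(scan/schedule/density/klm/phantom/acquire/recon/quantify), writes a resolved
config, log, and manifest per run, and fans one global seed out to stages via
`numpy.random.SeedSequence([seed, stage_id])` (all derived seeds < 2³¹), so a
stage rerun reproduces its slice of a full run. The CLI is a thin click layer
over the same calls.

## Problem sizes

Defaults are desk-scale by design: 512×512 density maps with the full
356,000-pulse schedule; 4096-point KLM grids; end-to-end image tests use
48–96-pixel grids, 64–96³-voxel phantoms, and reduced PRFs (hundreds to a few
thousand hertz), which exercise every code path of the full-size problem at
a few seconds per test.

## Known limitations

No piezo-tube hysteresis, cross-axis coupling, or whirl; no diffraction field
or depth-dependent sensitivity; no acoustic attenuation in tissue or coupling
films; lossless transducer layers by default; the forward model is linear and
noise-additive. The in-vivo figures of the source system (measured
resolutions, SNR, tumor-vs-normal morphometry) depend on animal data and are
outside what this simulator can or should reproduce; the corresponding
operations are implemented and validated on constructed ground truth instead.
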