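# Methods

This note records the models implemented in `chipscreen`, their assumptions,
the defaults that matter, and the design choices made where the underlying
publication record left the design open.

## Stokes–Einstein transport chain (`transport`)

Each solute is a hard sphere whose volume equals its molar volume: the radius
is r = ∛(3·MW/(4π·N_A·ρ)) with MW in g/mol and ρ in g/cm³ (converted to SI at
the constructor boundary), the diffusivity is D = kT/(6πμr), and the
characteristic time to diffuse a distance x is t = x²/(2D), the 1-D
mean-square-displacement time. The chain assumes dilute, spherical,
non-interacting solutes; no shape or hydration corrections are applied
(deliberately — these are design-table estimates, not measurements).

**Constants and defaults.** k = 1.380649×10⁻²³ J/K (exact); N_A = 6.022×10²³
1/mol, matching the 4-figure precision of the design tables this chain
regenerates. Default temperature is 310.15 K (cell-culture incubator).
The default viscosity is **1.01×10⁻³ Pa·s and is a calibration**: published
design tables for these molecules are stated as using water at 37 °C, but
they are only reproduced with a viscosity near the 20 °C value
(μ(37 °C) ≈ 0.69×10⁻³ Pa·s would raise every D by ~46%). We keep the value
that reproduces the tables, expose both temperature and viscosity as plain
arguments, and note the discrepancy here. Two published rows (carmustine,
lomustine) are additionally inconsistent with their own printed inputs at the
third significant figure; the strict regeneration test documents and
exercises this.

**Mean velocity.** v = (Q_total/n)/(w·h) for flow split over n identical
rectangular channels; with two 1 µL/min inlets over four 150×50 µm channels
this gives 1.11 mm/s, the capillary-like perfusion operating point.

## Absolute mixing index and profile metrics (`mixer`)

The AMI is the population coefficient of variation of the normalized
cross-width intensity profile, AMI = √((1/N)Σ(Iᵢ−⟨I⟩)²)/⟨I⟩. We use the
population (1/N) standard deviation, not the sample (N−1) form, because the
profile is an exhaustive pixel census of the cross-section, not a sample.
AMI is zero iff the profile is constant, invariant under intensity rescaling,
and strictly decreased by adding a positive constant — which is why
normalization references matter: they are explicit arguments (dye plateau →
1, chip background → 0, values clamped to [0,1]), with an optional min/max
auto mode that is off by default because it silently couples images.

Profile extraction takes the per-column mean of one colour channel inside a
half-open, 0-based rectangular ROI; the blue RGB channel is the default
because the visualization dye absorbs red/green. The slope metric is the
ordinary least-squares slope of intensity against position (1/µm); it is
signed by default, with a magnitude option, since the published usage does
not disambiguate. Dilution estimation linearly interpolates mean ROI
intensities between the designated 100% and 0% channels, which cancels any
affine camera response.

## Dilution-network model (`network`)

Merges are ideal flow-weighted mixing, c_out = Σqᵢcᵢ/Σqᵢ, which conserves
solute mass identically and keeps outputs inside the convex hull of the inlet
concentrations. The default weight model takes flow proportional to feed
width (valid when feed channels share height, length and pressure drop); a
rectangular-duct Poiseuille resistance (Fourier-series solution, default 20
odd terms — the series converges to <1% of the square-duct shape factor 28.45
by 10 terms) supports a resistance-network weighting when lengths are known.
The shipped two-stage width network (½ from 150+150 µm; ¼ from 50 µm dye +
150 µm buffer) reproduces the 1:½:¼:0 ladder; the physical device's full
interior routing is not published (a 75 µm feed appears in the fabrication
description whose role is not derivable), so the topology is an example
configuration, not hard-coded truth.

## FCS triplet model (`fcs`)

G(τ) = (1/N)·(1+τ/τ_D)⁻¹·(1+p²τ/τ_D)⁻½·(1+T/(1−T)·e^(−τ/τ_T)), the standard
3-D Gaussian confocal volume with a single-exponential triplet correction.
Some write-ups print the axial factor with a bare p rather than p²; the
standard p² form is the default and the literal variant is available
(`p_squared=False`) and tested. G(0) = 1/(N(1−T)); the normalized curve
G(τ)/G(τ₀) is independent of N.

Fitting is unweighted nonlinear least squares (lmfit/trust-region) with
bounds enforcing the parameter invariants (positivity, T ∈ [0,1)) rather
than penalties; any subset of parameters can be fixed, and the standard
protocol fixes p from the confocal-volume calibration
r₀ = √(4·D_known·τ_D). Optional 1/G² weighting is provided. On synthetic
curves with 2% multiplicative Gaussian noise, 50 log-spaced lags over 4
decades (10⁻⁷–10⁻³ s) around τ_D = 2.35×10⁻⁵ s, the median relative τ_D
error over 100 seeds is ≈2%.

## Fickian penetration (`penetration`)

c(x,t) = c₀(1−erf(x/2√(Dt))): a semi-infinite medium at constant surface
concentration, no drug consumption, binding or convection. The semi-infinite
assumption is retained even though the physical gel is 250 µm thick, because
the erf form is the model of record for this geometry; it underestimates
late-time interior concentration relative to a finite slab with a sealed
bottom, so threshold times are conservative. Time-to-threshold is solved by
Brent bracketing on t (relative tolerance 10⁻⁹), starting from the
characteristic time x²/4D and expanding decade-wise; the closed-form
inverse t = x²/(4D·erfinv(1−c/c₀)²) serves as an independent oracle in the
tests, not as the implementation.

Direct evaluation at 250 µm with the gel diffusivity 2.55×10⁻¹⁰ m²/s gives
1.71 mM (of 2 mM) at 1 h and 1.85 mM at 4 h; published statements of
">1.9 mM within 1 h" for the same setup are not reproduced by this model and
are treated as a discrepancy, not a target (reaching 1.9 mM at that depth
takes ≈8.7 h).

## Dose–response (`doseresponse`)

Viability is 100·N_L/(N_L+N_D). The dose–response model is a descending
Hill curve on **linear** concentration, V(c) = bottom +
(top−bottom)/(1+(c/EC50)^hill), chosen over the log-dose 4PL because screens
on these chips include a true zero-dose control, which the linear form
handles exactly (V(0) = top). A log-dose mode exists for positive-dose
designs. Default bounds keep viability physical (0 ≤ bottom, top ≤ 100,
hill > 0); EC50 is the dose at the midpoint between the fitted plateaus —
note this differs from "dose at 50% absolute viability" whenever the
plateaus are not 100/0, which is why published EC50s under unstated model
forms are treated as soft brackets. R² is computed on the untransformed
viability scale. Rising-with-dose series are fitted but flagged.

## Synthetic data (`synthetic`)

Every generator is a pure function of (spec, seed) and returns its exact
ground truth:

- **Mixing images** (default 200×40 px, 150 µm channel): the cross-width
  concentration is the erf solution of two-stream interdiffusion after a
  residence time L/v (defaults: dye diffusivity 3.31×10⁻¹⁰ m²/s, 18.5 mm
  serpentine, 1.11 mm/s at the 1 µL/min operating point), mapped linearly
  into the blue channel of an RGB image between background (20) and dye (200)
  levels with additive Gaussian noise. This exercises the blue-channel
  extraction path of `mixer`.
- **Cell fields** (default 256×256 px): disk "cells" of radius 5 px placed
  uniformly at random without overlap (minimum centre separation 2r+3 px so
  rasterized disks never touch under 8-connectivity, keeping counting exact);
  live cells in channel 0, dead in channel 1. The paired counter thresholds
  each channel, labels 8-connected components and drops those below a
  minimum area.
- **FCS curves**: the triplet model with multiplicative Gaussian noise of a
  stated fraction.
- **Viability tables**: the Hill model with additive Gaussian noise, clamped
  to [0,100]%.

What these emulate — and do not: the images have uniform illumination, no
point-spread blur, no bleaching and perfectly disk-shaped cells; the FCS
noise is uncorrelated across lags, unlike real correlator noise. Passing the
closed-loop tests therefore demonstrates correctness of the analysis chain
under the stated models, not robustness to real-microscopy artefacts.

## Pipeline and problem sizes

The demo pipeline runs every stage on synthetic inputs with per-stage seeds
derived deterministically from one global seed, and its outputs are
byte-identical across reruns of the same config. Simulation studies in the
test suite use 30–100 seeds per study and images up to 256×256 px — sizes
chosen so the full closed-loop suite completes in seconds while leaving the
medians it asserts stable to well under the tolerances tested.
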