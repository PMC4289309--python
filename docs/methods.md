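# Methods

This note records the models implemented in `sprimage`, the assumptions
behind them, the parameters that matter, and the choices made where the
design was genuinely open.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Multilayer reflectance

Reflectance of the sensor stack is computed with the characteristic-matrix
(Abelès) solution for isotropic stratified media with complex
permittivities, in the e^(−iωt) convention (absorbing media have
Im ε ≥ 0, transverse wavevectors take the Im k_z ≥ 0 branch so fields decay
away from interfaces).  The optical admittance is η = k_z for s- and
η = ε/k_z for p-polarization; both polarizations coincide at normal
incidence by construction.  The test suite checks the implementation
against an independently coded Parratt recursion (the classical alternative
formulation) to 10⁻¹⁰ on random 3–5 layer stacks, and checks R + T = 1 for
lossless stacks to 10⁻¹⁰.

The sensor stack is the 3-layer glass/gold/water model: a 1.78-index
coverslip, a 45 nm gold film, and water.  The ~1 nm chromium adhesion layer
under the gold is deliberately ignored — the angle scans this instrument
class records are routinely fit with the 3-layer model, and chromium's
effect is a small, table-dependent shift absorbed by the fitted gold
thickness.

**SPR minimum search**: coarse 0.05° grid beyond the critical angle
followed by bounded local refinement to 10⁻³° (requirement: ≤ 0.01°).  A
stack with no sub-unity minimum beyond the critical angle (e.g. a lossless
stack in total internal reflection) reports "absent" rather than raising.

**Operating point**: imaging happens slightly shallow of the minimum, at
R ≈ 0.1 on the descending flank, where the response to small index changes
is linear and positive.  At 480/515 nm the gold is lossy enough that the
dip does not reach 0.1; the operating point then falls back to
R_min + 0.05, still on the shallow flank.  `operating_reflectance` is a
config parameter (default 0.1).

## Optical constants

The paper-grade gold tabulations in the visible disagree appreciably
(coupling angle shifts of ~1–2°, decay lengths by ~10–20%).  The built-in
table is a smoothed, rounded visible-range compilation for sputtered gold
films of the handbook type, with ε(620 nm) ≈ −12.2 + 1.7i — the constants
consistent with this instrument class's calibration (coupling angle ≈ 54°
at 620 nm through n = 1.78 glass, plasmon propagation length ≈ 3 μm).
Johnson–Christy-type tables, with ε′(620) ≈ −9.7, put the minimum near 56°
and L_x near 3.6 μm instead.  The table is therefore swappable: any
`dispersion_tables` entry in the run config replaces it, and every report
names the table used.  Dispersion is interpolated linearly in n and k
separately (not in ε); queries outside the tabulated range raise.  Water is
tabulated as a real index (absorption negligible at these thicknesses).

## Evanescent-field quantities

* Penetration depth: Lₚ = (λ/2π)·√|Re ε_m + ε_d|/ε_d, the 1/e length of
  the plotted decay I(z) = I₀e^(−z/Lₚ).  This closed form is, strictly,
  the *amplitude* 1/e depth 1/|k_z|; the field intensity decays twice as
  fast.  The instrument literature uses the closed form as "the"
  penetration depth and plots I(z) with it, and this package follows that
  convention throughout — no factor of 2 is applied anywhere.
* Propagation length: L_x = 1/(2·Im k_sp), with the complex square root on
  the Im ≥ 0 branch; a lossless metal reports L_x = ∞.
* Diffraction limit: 0.61·λ/NA.

One consequence of the amplitude/intensity conflation is checked and
documented rather than hidden: a first-order Fresnel perturbation (a
weak-contrast bead) responds to |E(z)|², so the 4-layer model's ΔR(z)
decays with length Lₚ/2, not Lₚ.  The test suite verifies this exponent
numerically.  The bead *detection-depth* experiment is unaffected because
its threshold is calibrated operationally (below).

## Back focal plane

Radial position in the BFP encodes the incident angle through the Abbe
sine mapping r/R = sin θ/sin θ_max.  θ_max defaults to 60°, the calibrated
periphery of this instrument class, deliberately decoupled from the
NA/n-derived maximum (≈68°): the aperture-edge calibration is an instrument
property.  Azimuth 0° lies along +x (the polarization axis, where the SPR
dip appears), increasing counter-clockwise.  Crescent masks include pixels
by center radially; at the azimuthal ends a pixel counts only when the arc
covers at least half its angular footprint, so a vanishing arc is empty.

`fit_fresnel_scan` fits a measured angle scan with the 3-layer model over
three free parameters — gold thickness, a multiplicative intensity scale
(camera counts per reflectivity unit), and a small angle offset — by
trust-region least squares.  The intensity scale makes the fit invariant to
overall rescaling and is what converts BFP line-scan counts to reflectivity
units.  Non-convergence is flagged on the result object, never silent.

## Synthetic scenes

**Bead model.** A sphere of radius r₁ resting on the gold is treated
ray-locally: under each pixel at in-plane distance ρ from the contact
point, the stack is glass/gold/water-gap(z)/bead with
z(ρ) = r₁ − √(r₁² − ρ²), the bead acting as a semi-infinite slab of its
bulk index.  This matches the layer-model picture used to interpret such
images; Mie scattering and curvature corrections are out of scope.  R(z) is
tabulated on a dense grid (z = 0 exact) and interpolated per pixel; beyond
~15 penetration depths the 4-layer model has converged to the 3-layer
background (checked to 10⁻⁶ at 20·Lₚ).

**PSF.** Anisotropic: a Gaussian of FWHM 0.30 μm along x (perpendicular to
plasmon propagation) and, along y, the same Gaussian convolved with a
one-sided exponential tail of 1/e length 0.4543 μm — the tail length was
solved once so the rendered y-profile FWHM is 0.60 μm, the measured
anisotropy of this instrument class at 620 nm.  For multi-wavelength
scenes the PSF scales physically (`instrument_psf`): the Gaussian width ∝ λ
(diffraction) and the tail ∝ the theoretical propagation length L_x(λ),
capped at its 620 nm value because the crescent illumination's azimuthal
angle spread — not the plasmon — sets the observed tail at and beyond
620 nm.  At 480 nm, where gold is lossy and L_x ≈ 0.15 μm, the tail nearly
vanishes; applying the 620 nm tail there would be physically wrong.

**Illumination and noise.** A smooth low-order polynomial field (a few %)
multiplies both the p and s frames, so dividing p by s removes it — the
purpose of the s reference.  Noise is i.i.d. additive Gaussian in
reflectance units, σ/√N for N averaged frames, applied after the PSF blur;
camera shot noise is not modeled.  Bright-field frames get a fixed small
noise (≤ 0.005 of the unit background): they are high-SNR transmission
exposures, not SPR frames.  Every render is bit-reproducible under its
seed.

**Bright-field model.** A 1-pixel dark ring at the projected radius r₁
convolved with a Gaussian of the diffraction-limit width — enough for the
ring-centerline radius measurement the pipeline needs, nothing more.

## Measurement pipeline

1. p/s division (pixels where s falls below 10⁻⁶ of its median are masked);
2. scaling by the model s reflectance at the operating angle, returning
   reflectivity units (in the instrument this scale comes from the Fresnel
   fit of the BFP scan);
3. ΔR conversion against a background region (the annulus itself by
   default; its mean is 0 afterwards to machine precision);
4. background σ from the annulus between the bead ROI circle and the circle
   whose *diameter* is 10 μm larger (sample SD, ddof = 1);
5. r₂ from the count of pixels above k·σ (k = 3) inside the ROI,
   r₂ = √(N·A_px/π).  All above-threshold pixels count, as in the original
   ImageJ recipe; an optional largest-connected-component mode exists but
   is off by default;
6. r₁ from the bright-field ring (radial profile minimum, parabolic
   sub-bin refinement over the whole frame — the ring lies far outside the
   SPR footprint);
7. depth d = r₁ − √(r₁² − r₂²), in nm.

The widely printed bead relation r₁² = r₂² + (r₂ − d)² is geometrically
inconsistent (it has no real solution for small observed chords); the
chord of a surface-resting sphere gives r₁² = r₂² + (r₁ − d)², i.e. the
form implemented, and the forward relation r₂ = √(d(2r₁ − d)) inverts it
exactly (tested to 10⁻¹² on 10⁴ random pairs).

FWHM estimation uses a baseline equal to the median of the profile's outer
quartiles (the choice is this package's; none is standardized) and linear
interpolation of the half-maximum crossings.

## The recovery experiment (`experiments.py`)

The in-silico restatement of the bead calibration: for each condition the
per-frame noise is calibrated so that the *noise-free rendered* (i.e.
PSF-blurred) ΔR image has exactly the Lₚ-chord area π·Lₚ(2r₁ − Lₚ) above
the 3σ threshold — the operational sense in which "the 3σ threshold sits at
the 1/e depth" for a pipeline that measures areas.  The p/s division
propagates noise from both frames, so the per-frame level is
σ_eff·√N_frames/√(1 + (R_p/R_s)²).

The default panel pairs materials with their physical sizes: silica
(n = 1.42, r₁ = 3.05 μm) and polystyrene (n = 1.59, r₁ = 2.85 μm) at the
camera's native 65 nm pixel scale, PMMA (n = 1.48) and Sephacryl
(n = 1.345) as 30 μm spheres at 0.2 μm pixels in a field of view large
enough to contain the bright-field ring.  Bead ROIs extend 2 μm beyond the
expected footprint.  Six wavelengths (480–670 nm), ten seeds per condition;
the whole study runs in well under a minute on one CPU.  These problem
sizes are the package's own choice of a study large enough to constrain
the 15% agreement bands while staying desk-scale.

What passing shows — and what it does not: the synthetic scenes share the
pipeline's forward model (4-layer Fresnel, ray-local bead, Gaussian noise).
Agreement therefore validates the *pipeline and geometry inversion*, not
the bead optics against nature; real images add gold roughness, coverslip
inhomogeneity, bead polydispersity and scattering that the generator does
not emulate.

## Known limitations

* Scalar PSF model; no rigorous vector diffraction or partially coherent
  DLP illumination physics.
* The ray-local slab approximation overestimates contrast for strongly
  curved (small) beads near grazing field angles.
* ΔR saturates for high-index beads (the response is nonlinear in Δn);
  the pipeline measures areas at threshold, which is insensitive to the
  saturation, but absolute ΔR amplitudes should not be interpreted
  linearly.
* Gold tables vary; all angle- and depth-type outputs inherit that
  uncertainty (~1–2° / ~10–20%), which is why every report names its table.
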