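# Methods

`tilt3d` is an in-silico single-molecule localization microscope built
around two ideas: a **tilted Gaussian light sheet** that excites only a
thin section of the sample (cutting out-of-focus background), and
**pupil-engineered point spread functions** that encode each emitter's
axial position in the shape of its image — a double-helix (DH) PSF for
single molecules over a ~2 µm range, and tetrapod PSFs for fiducial beads
over 6–10 µm. This note records the models, the defaults, the numerical
choices, and what the synthetic experiments do and do not demonstrate.

## Optical model

Image formation is scalar Fourier optics for an isotropic emitter. The
pupil field of an emitter at depth z (relative to the nominal focal
plane) is

    U(u, v; z) = A(u, v) · exp(i [ φ_mask(u, v) + k z √(n² − NA² ρ²) ])

with `A` the unit-disc aperture, `ρ` the normalized pupil radius,
`k = 2π/λ`, immersion index `n = 1.518` (oil; sample/coverslip index
mismatch is ignored), NA = 1.4, magnification 100. Lateral displacement
is a linear pupil phase ramp. The image intensity is `|FT U|²`,
evaluated as an explicit scaled DFT (a small matrix product), which
samples the image on any requested pixel grid — camera pixels (16 µm
pitch / 100× = 160 nm in the object plane) or oversampled grids — with
no interpolation. Intensity is point-sampled at pixel centers rather
than integrated over pixels; the PSF varies slowly over a 160 nm pixel
and the same convention is used consistently in rendering, templates and
fitting, so no mismatch bias arises.

Normalization is by total emitted energy (Parseval): a rendered window
sums to the fraction of the emitter's photons it captures, so photon
budgets are exact. A unit-sum option exists for display. Windows that
clip more than 5% of the energy raise by default.

The Fourier-plane field diameter follows the Abbe sine condition,
`d_E = 2 f NA / √(M² − NA²)`: 2.5 mm for the 90 mm 4f lens used with
transmissive masks and 4.2 mm for the 150 mm lens used with a deformable
mirror (DM).

### Shipped phase masks

* **Clear** — zero phase; the Airy-type reference PSF.
* **Double helix (2 µm)** — commercial DH masks are proprietary, so the
  shipped mask is a spiral-Fresnel-zone rotating-PSF design: the pupil is
  split into L concentric equal-area zones, zone ℓ carrying an azimuthal
  vortex phase of odd charge 2ℓ−1. Odd charges make the field change
  sign under a half turn, so the intensity shows two diametrically
  opposite lobes; defocus advances adjacent zones by c/L radians (c the
  quadratic defocus coefficient), rotating the lobe pair **linearly** in
  z at rate c/(2L). L is the smallest integer keeping the rotation at
  the range edge below ~63°, so the full swing stays under 180° and the
  angle→z map is single-valued. For the 2 µm mask at 670 nm this gives
  L = 3, a lobe separation of ~850 nm, and ~160° total rotation over
  ±1 µm. All calibrations are generated self-consistently from this
  mask, so no downstream step assumes the commercial pattern.
* **Tetrapod (6 and 10 µm)** — an astigmatism-family Zernike recipe:
  primary (Z6) plus secondary (Z12) astigmatism with amplitudes
  proportional to the defocus swing over the requested range
  (fractions 0.55 and −0.20 of c_half). This is a stand-in for
  CRLB-optimized tetrapod designs: it is smooth (DM-realizable), its
  footprint grows monotonically with |z|, and its template stack is
  z-distinguishable across the nominal range, which is what the fiducial
  pipeline needs; it does not claim image-level equality with any
  published mask.

### Cramér–Rao bounds

`optics.crlb` computes the Poisson pixel-model Fisher information with
numerical PSF derivatives (x, y: ±2 nm; z: ±4 nm central differences),
treating the photon count — and the background, when nonzero — as
nuisance parameters. The clear aperture at focus correctly reports an
unbounded z variance (symmetric defocus carries no first-order z
information); the DH mask's z bound varies by less than 2× over its
2 µm range.

## Illumination

The sheet propagates along an axis tilted 10° downward about the width
axis. At the waist it has a 1/e² thickness radius of 2.1 µm and a fixed
1/e² half-width of 19 µm; thickness follows the hyperbolic Gaussian-beam
law parameterized **directly** by the configured confocal parameter
(73 µm). Waist and confocal parameter are deliberately independent
inputs: the printed pair is inconsistent with an ideal Gaussian beam at
647 nm, and treating both as measured properties reproduces the real
(mildly aberrated) sheet. The amplitude factor w₀/w(ξ) conserves power
across the sheet normal. Epi-illumination is z-uniform over the cell
(the slow lateral Gaussian of a widefield beam is ignored; comparisons
are at the field center).

Out-of-focus background integrates emitter density × illumination
intensity over the labeled volume by deterministic quadrature (20 nm
steps). For a laterally uniform slab the defocused-PSF lateral spread
redistributes but conserves energy within a pixel column, so each layer
contributes its full areal rate — a conservative estimate that needs no
blur kernel. On a 10 µm slab with waist and focal plane at the slab
center this predicts a 3.7× epi→sheet background reduction, and the
same factor in single-frame SBR at matched signal.

## Synthetic microscope

Phantoms: `lamina_shell` (emitters uniform on a sphere, radial offsets
from a **truncated Gaussian whose FWHM is the nominal thickness** — so
the rim-width quadrature law is exact), `mito_cylinder` (hollow cylinder,
uniform bounded radial offsets), `bead_field`/`points` (explicit
positions). Counts are Poisson in area × density; everything is
deterministic given the seed.

Photoswitching is a three-state (dark/on/bleached) per-frame Markov
model with rates in s⁻¹ converted through the 50 ms exposure. Defaults
(on→off 10 s⁻¹, off→on 0.02 s⁻¹, bleach 0.1 s⁻¹, 95% initially dark)
keep the active set sparse enough for the wide DH footprint; UV
reactivation frames multiply the dark→on rate of the following frame.

The acquisition schedule interleaves roles 1-based within a run: every
20th frame images the fiducial channel; after frame 10 000 every 100th
frame is a UV reactivation frame (taking precedence on coincidence).
Slices are (sheet offset, focal plane) pairs stepped together in 1 µm
increments.

The EM-CCD chain per pixel: expected photons → quantum efficiency →
Poisson shot noise → gamma-distributed EM amplification (shape = electron
count, scale = gain 186; the standard model of the multiplication
register, excess noise factor √2) → Gaussian read noise (3 e⁻ RMS) →
12 e⁻/ADU conversion → +100 count offset → rounding and 16-bit clipping.
The 12 e⁻/ADU sensitivity is a typical EM-CCD value and keeps a
1000-photon pixel within the 16-bit range at gain 186. Dark calibration
averages shutter-closed frames (300 by default) and the mean map is
subtracted (clamped at zero) before analysis; photon conversion is
counts × conversion / gain.

Stage drift is linear ramp + Gaussian random walk per axis. Live axial
feedback is simulated through a hook called after each fiducial frame
(one interleave period of latency), with steps clamped to ±200 nm so a
single bad fix cannot run the objective away. The ground-truth log
(emitter states, drifted positions, expected photons per frame) fully
determines every pre-noise image; `expected_frame` re-renders it
bit-for-bit.

Fiducial beads carry a fixed photon budget per fiducial frame
(8×10⁴ in the multi-slice experiment — chosen to stay below camera
saturation even where the tetrapod is compact).

## Double-helix localization

Detection is a matched filter: the background-subtracted frame is
convolved with two-displaced-Gaussian kernels over six trial
orientations at the calibrated lobe separation; the per-pixel maximum
response is thresholded (median + 6 robust σ by default) and local
maxima become ROI centers.

The estimator is a least-squares fit of two isotropic Gaussians plus a
constant (8 parameters); lobes collapsing within one pixel are rejected.
The lobe midpoint gives (x, y) (minus a calibrated per-z midpoint-wobble
correction), and the lobe-pair angle — measured modulo 180° in the
row = +y frame convention — inverts a 5th-order polynomial fitted to the
bead-scan angle table, restricted to its maximal strictly monotone
interval around focus (≥ 2.2 µm for the shipped mask). Photons
integrate both Gaussians.

An optional Poisson maximum-likelihood polish refits (x, y, z, N, b)
against the true rendered PSF: templates every 30 nm in z, 2×
oversampled in x/y, interpolated linearly in z and spline-shifted
laterally, optimized by Nelder–Mead from the double-Gaussian seed. The
plain double-Gaussian estimator reaches 1.2–1.8× the CRLB on this mask;
the polish reaches it within ~10% and removes the residual angle-model
bias near the range edges. An iteratively model-reweighted least-squares
mode (`weighting="poisson"`) sits between the two.

Quality filters (all configurable): normalized fit residual ≤ 0.25,
lobe asymmetry ≤ 2.5, separation within 20% of the calibration, minimum
photons 200, z inside the calibrated range, and an optional trim of the
outer working range (|z| ≤ 900 nm in the multi-slice experiment, which
rejects half-turn angle-wrap errors; the 1 µm slice overlap keeps
coverage complete). Every drop is tagged with its reason.

## Tetrapod fiducial calibration and tracking

Calibration is Gerchberg–Saxton-style phase retrieval from a
through-focus bead stack: alternating projections between the measured
plane magnitudes and the pupil constraint (unit amplitude in the
aperture), with a light complex-field Gaussian smoothing (σ = 0.5
samples; DM phases are smooth) between iterations; up to 150 iterations,
stopping after 10 without relative improvement above 1e−5. Retrieval
runs on the transform-native image grid (pixel = λR/(N·NA) ≈ 108 nm),
where the pupil↔image map is a unitary FFT and inversion is exact; the
synthetic bead scan is rendered on that grid. The retrieved pupil is a
gauge fix — piston/tip/tilt leave images unchanged — so the acceptance
metric is image-domain NRMSE (< 0.5% noiseless, < 5% at 10⁵
photons/plane), never pointwise phase equality. Tracking templates are
then re-rendered from the retrieved pupil on the camera grid (and a 2×
fine grid), extending 0.5 µm beyond the scan so feedback excursions stay
in range.

Tracking: normalized cross-correlation against the template stack
(searching ±0.6 µm around the previous fix when available) gives an
integer-pixel peak and coarse z; a continuous Nelder–Mead refinement
then maximizes the Pearson correlation of the cropped frame against
z-interpolated, sub-pixel-shifted fine templates, jointly over
(x, y, z). The optimizer starts at the known integer offset of the bead
within the crop (nonzero when the crop is clipped at a frame border —
skipping this was a real failure mode). A correlation floor of 0.35
flags dropouts, which hold the last position as seed and are
interpolated in the output track. Round-trip bias is < 2 nm noiseless
anywhere in the range; at 10⁶ photons the Monte-Carlo scatter is
sub-nm laterally and ~0.3 nm axially for frames drawn from the
calibration's own model.

## Drift correction and stitching

Fiducial tracks sampled every 20th frame are interpolated linearly to
all frames (drift is slow against the interleave) and subtracted. The
trace reference extrapolates a linear fit of the **first eight** track
samples to frame 0: drift accumulated before the first fiducial frame
would otherwise offset the whole reconstruction, while long fit windows
let the random-walk component corrupt the intercept.

Slice stitching estimates the residual inter-slice offset by
cross-correlating z histograms (10 nm bins, parabolic sub-bin peak) of
the overlap region — restricted to the intersection of both slices'
well-localized bands (focal ± 0.8 µm) so coverage fall-off does not skew
the correlation — chained from the bottom slice, optionally initialized
by shared-fiducial offsets. For structures with little blind z profile
in the overlap (a spherical shell's z histogram is flat — Archimedes'
hat-box theorem — so the correlation returns noise-level offsets of
±20–50 nm at desk-scale counts), `refine=False` applies the
shared-fiducial offsets alone; a bead tracked through all slices pins
the registration to a few nm. The multi-slice experiment uses this
fiducial-anchored mode; the histogram refinement is validated on
structured overlaps.

## Rendering and measurement

Reconstructions are voxel histograms, optionally convolved with an
isotropic Gaussian (per-point precision; mass-conserving). Line scans
average across a configurable width and fit Gaussian + constant,
reporting FWHM = 2.3548 σ. Per-frame SBR is (peak − background) /
background with the background from a median over a 2–3 footprint-radius
annulus.

## The multi-slice shell experiment

The end-to-end run images a 1.2 µm-radius, 150 nm-thick spherical shell
(the nuclear-lamina analogue, 60 emitters/µm²) centered 3 µm above the
coverslip, in two slices 1 µm apart (focal planes at 2.5 and 3.5 µm,
sheet stepped with the focus), 1000 frames per slice, with
(0.15, −0.1, 0.2) nm/frame linear drift plus a 1 nm/frame random walk —
a few hundred nm over the run — live axial feedback from a tetrapod
fiducial at (−6, −6, 1) µm, post-hoc 3D drift correction from the same
bead, fiducial-anchored stitching, and reconstruction metrics:

* axial shell-center bias from a trimmed least-squares sphere fit;
* hollowness: center/rim density ratio of the xz cut;
* rim width: 3σ-clipped spread of lateral radii in the ±300 nm equator
  band, where the shell surface is normal to the lateral plane and
  curvature sag over the band is negligible.

The rim-width check compares FWHM² against t² + (2.3548 σ)², where t is
the true lateral-radius spread of **the emitters actually rendered in
the band** (blinking activates a subset, with varying weights — the
simulator's ground truth makes the comparison exact rather than diluted
by labeling-sample luck) and σ is the pooled within-emitter repeat
scatter of those radii. Across seeds this holds within ±7%, the axial
center bias stays under 20 nm, and the annulus center/rim ratio is
below 0.1.

Activation is kept sparse (off→on 0.004 s⁻¹) because the wide DH
footprint makes neighbor halos bias lobe fits; at the shell poles the
surface is horizontal and projected emitter density diverges, so
crowding there is the leading residual error in the axial center.

## What the synthetic data does not capture

Vectorial/dipole emission, index-mismatch and system aberrations,
spectral crosstalk between the two logical detection channels, sCMOS-style
structured noise, fluorophore photophysics beyond three states, emitter
motion during exposure, and autofluorescence structure. Passing tests
demonstrate the internal consistency and statistical efficiency of the
pipeline under the stated models, not performance on real cells; the
real instrument's printed precisions depend on photon budgets that are
not reproduced here.

## Problem sizes

Desk-scale defaults were chosen so the full test suite and the
experiment drivers complete in minutes on one core: 256² pupil grids,
25–64 pixel ROIs, tens of calibration planes, hundreds to a couple of
thousand frames per experiment, 16–120 Monte-Carlo repeats per
condition. All are parameters.
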