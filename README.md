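# tilt3d

Tilted light-sheet single-molecule localization microscopy, in silico:
an instrument simulator and the full 3D super-resolution analysis
pipeline that goes with it.

## The problem

3D single-molecule super-resolution imaging of whole mammalian cells
needs two things at once: **low background**, because out-of-focus
fluorophores drown single molecules under epi-illumination, and a
**long axial capture range**, because a nucleus is many micrometres
thick while a conventional PSF localizes over a few hundred nanometres.
The design modeled here solves both by combining a Gaussian light sheet
tilted ~10° toward the coverslip (so cells can be sectioned down to the
glass with a high-NA detection objective) with pupil-engineered PSFs: a
double-helix (DH) PSF whose two lobes rotate with emitter depth —
the lobe midpoint gives (x, y), the lobe angle gives z over ~2 µm — and
tetrapod PSFs that encode 6–10 µm of depth for fiducial beads, enabling
live axial drift locking and post-hoc 3D drift correction from any bead
height. Thick structures are covered by stepping sheet and focal plane
together in 1 µm slices and stitching the overlapping slabs.

The package is for microscopy method developers and analysts: it
generates realistic EM-CCD frame streams of blinking emitters on 3D
phantoms (nuclear-lamina shells, mitochondria-like cylinders) under
epi or tilted-sheet illumination with the interleaved single-molecule /
fiducial / reactivation frame schedule, and then analyzes them —
detection, double-Gaussian lobe fitting, angle→z inversion,
phase-retrieved tetrapod calibration, template tracking, drift
correction, slice stitching, rendering — with every step testable
against ground truth and Cramér–Rao bounds.

Core relations:

* Fourier-plane field size (Abbe sine): `d_E = 2 f NA / √(M² − NA²)`
* DH depth encoding: `z = P⁻¹(θ)` with θ the lobe-pair angle and P a
  polynomial calibrated from a bead z-scan; `(x, y)` = lobe midpoint
* Localization precision floor: Poisson-model Cramér–Rao bound of the
  pixelated engineered PSF
* Rendered-structure width: `FWHM² ≈ t² + (2.3548 σ)²` for structure
  thickness t and localization precision σ

## Worked example

```python
import numpy as np
from tilt3d import optics, dhloc, pipeline

cfg = optics.OpticalConfig()
print("d_E(150 mm) =", round(optics.fourier_plane_diameter(cfg), 1), "mm")

# shipped 2 µm double-helix mask + bead-scan calibration
mask, cal = pipeline.default_dh_calibration(cfg)
lo, hi = cal.z_valid_nm
print(f"DH calibration: valid z range {lo:.0f}..{hi:.0f} nm, "
      f"lobe separation {cal.mean_separation_nm:.0f} nm")

# localize one noisy emitter placed at (40, -30, 500) nm
roi = 3000 * optics.psf_at(mask, 0.5, cfg, 160.0, 25,
                           shift_nm=(40.0, -30.0), max_clip=None) + 10
rng = np.random.default_rng(0)
fit = dhloc.fit_double_gaussian(rng.poisson(roi).astype(float), 160.0)
rec = dhloc.lobe_pair_to_xyz(fit, cal)
print(f"one noisy emitter at (40, -30, 500): "
      f"x={rec['x_nm']:.0f} nm, y={rec['y_nm']:.0f} nm, z={rec['z_nm']:.0f} nm, "
      f"{rec['photons']:.0f} photons")

cr = optics.crlb(mask, 3000, 10, 0.5, cfg)
print(f"CRLB at this condition: x {cr['x_nm']:.1f} / y {cr['y_nm']:.1f} "
      f"/ z {cr['z_nm']:.1f} nm")
```

prints

```
d_E(150 mm) = 4.2 mm
DH calibration: valid z range -1100..1100 nm, lobe separation 857 nm
one noisy emitter at (40, -30, 500): x=40 nm, y=-29 nm, z=509 nm, 1590 photons
CRLB at this condition: x 4.5 / y 4.0 / z 8.5 nm
```

The 4.2 mm is the electric-field diameter at the Fourier plane for the
150 mm 4f lens (matching a deformable mirror's active area); the
calibration shows the DH angle→z map is single-valued over 2.2 µm; the
single-shot estimate lands within ~10 nm of the true 3D position (the
double-Gaussian estimator reports the photons it captures in its two
lobes, about half the emitted total for this mask); and the CRLB rows
give the information-theoretic floor at 3000 photons over 10
background photons/pixel.

Higher-level experiments live in `tilt3d.pipeline`: paired epi vs
light-sheet precision comparisons on a labeled slab
(`illumination_precision_comparison`), localization round trips against
the CRLB over a position grid (`localization_grid_roundtrip`), tetrapod
tracking at arbitrary bead heights (`tetrapod_tracking_roundtrip`), and
the full two-slice lamina-shell acquisition with drift, live feedback,
drift correction, stitching and reconstruction metrics
(`lamina_multislice_run`). `docs/methods.md` documents the models and
defaults.

A CLI mirrors the library for shell use:

```
tilt3d psf --mask dh --range 2 --z-min -1.1 --z-max 1.1 --step 0.05 --out dhcal.tif
tilt3d simulate --out run/ --frames 200 --seed 1
tilt3d localize --calib dhcal.tif --frames run/frames.tif --out locs.csv
tilt3d stitch --slices s0.csv s1.csv --out merged.csv
tilt3d render --locs merged.csv --out recon.png
```

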