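"""Tetrapod fiducial calibration and 3D tracking over a 6-10 µm axial range.

The tetrapod PSF encodes z over many micrometres, so a fiducial bead can
be tracked from any height — at the coverslip below the cell or inside it
— while the focal plane stays at the structure of interest.

Calibration is phase-retrieval style: given a through-focus intensity
stack of a single bead, alternating projections between the measured
plane magnitudes and the pupil constraint (unit amplitude inside the
aperture, smooth phase) recover a pupil phase whose forward model
reproduces the stack.  The retrieved pupil is a gauge fix, not ground
truth — piston/tip/tilt and a conjugation ambiguity leave the images
unchanged — so image-domain agreement is the acceptance metric.

Retrieval runs on the transform-native image grid (pixel = lambda R / (N NA)),
where the pupil-to-image map is a unitary FFT and inversion is exact; the
tracking template stack is then re-rendered from the retrieved pupil on
the camera pixel grid.

Tracking matches each fiducial frame against the template stack by
normalized cross-correlation: the best-z template (with parabolic sub-step
interpolation over z) gives z; the correlation peak position (parabolic
sub-pixel) gives x, y.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage

from tilt3d import optics

__all__ = [
    "TetrapodCalibration",
    "FiducialTrack",
    "retrieve_pupil",
    "render_templates",
    "track_fiducial",
    "track_stream",
    "track_quality",
]


def _fft2c(x: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(x), norm="ortho"))


def _ifft2c(x: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(x), norm="ortho"))


def native_pixel_nm(grid: optics.PupilGrid, config: optics.OpticalConfig) -> float:
    """Image pixel of the unitary pupil<->image FFT pair, nm."""
    return 1.0 / (grid.n_samples * grid.freq_spacing(config))


@dataclass
class TetrapodCalibration:
    """Retrieved pupil phase plus the tracking template stack."""

    pupil_phase: np.ndarray
    grid: optics.PupilGrid
    config: optics.OpticalConfig
    wavelength_nm: float
    z_range_um: tuple[float, float]
    image_error: float  # final normalized RMS image-domain error
    template_z_um: np.ndarray = dc_field(default=None)
    templates: np.ndarray = dc_field(default=None)  # (nz, n, n) camera-pixel
    template_pixel_nm: float = 160.0
    oversample: int = 2
    fine_templates: np.ndarray = dc_field(default=None, repr=False)

    def interp_template(self, dx_px: float, dy_px: float, z_um: float) -> np.ndarray:
        """Camera-grid template at continuous (x, y, z).

        Linear interpolation between fine-grid z planes, cubic-spline
        sub-pixel shift on the oversampled grid, then subsampling at the
        camera-pixel centers (point-sampled pixel convention).
        """
        tz = self.template_z_um
        z = float(np.clip(z_um, tz[0], tz[-1]))
        i = int(np.clip(np.searchsorted(tz, z) - 1, 0, len(tz) - 2))
        w = (z - tz[i]) / (tz[i + 1] - tz[i])
        plane = (1.0 - w) * self.fine_templates[i] + w * self.fine_templates[i + 1]
        os = self.oversample
        shifted = ndimage.shift(plane, (dy_px * os, dx_px * os), order=3, mode="nearest")
        n = self.templates.shape[1]
        off = len(plane) // 2 - os * (n // 2)
        return shifted[off::os, off::os][:n, :n]


def _forward_stack(
    pupil_phase: np.ndarray,
    aperture: np.ndarray,
    defocus: np.ndarray,
    norm: bool = True,
) -> np.ndarray:
    """Model intensity stack on the native grid for each defocus phase."""
    p = aperture * np.exp(1j * pupil_phase)
    out = np.empty((len(defocus), *pupil_phase.shape))
    for k, dph in enumerate(defocus):
        e = _fft2c(p * np.exp(1j * dph))
        out[k] = np.abs(e) ** 2
    if norm:
        out /= out.sum(axis=(1, 2), keepdims=True)
    return out


def retrieve_pupil(
    stack: np.ndarray,
    z_um: np.ndarray,
    config: optics.OpticalConfig | None = None,
    grid: optics.PupilGrid | None = None,
    max_iter: int = 150,
    tol: float = 1e-5,
    smooth_sigma_px: float = 0.5,
    template_range_um: tuple[float, float] | None = None,
    template_step_um: float = 0.05,
    template_pixels: int = 64,
    template_pixel_nm: float | None = None,
) -> TetrapodCalibration:
    """Recover the pupil phase from a through-focus bead stack.

    ``stack`` is (nz, N, N) intensity on the native grid (see
    ``native_pixel_nm``); plane normalization is handled internally.
    Alternating projections: impose measured magnitudes in the image
    domain, unit-amplitude aperture support in the pupil domain, and a
    light complex-field Gaussian smoothing (deformable-mirror phases are
    smooth).  Raises on stagnation without improvement.
    """
    from scipy import ndimage

    config = config or optics.OpticalConfig()
    grid = grid or optics.PupilGrid()
    z_um = np.asarray(z_um, dtype=float)
    if stack.shape[0] != len(z_um):
        raise ValueError("stack and z grid disagree")
    if stack.shape[1] != grid.n_samples:
        raise ValueError("retrieval stack must be on the native pupil grid")

    meas = stack / stack.sum(axis=(1, 2), keepdims=True)
    mags = np.sqrt(meas)
    aperture = grid.aperture()
    defocus = np.stack([optics.defocus_phase(grid, config, z) for z in z_um])
    dfactors = np.exp(1j * defocus)

    pupil = aperture.astype(complex)
    best_err = np.inf
    stall = 0
    for it in range(max_iter):
        acc = np.zeros_like(pupil)
        for k in range(len(z_um)):
            e = _fft2c(pupil * dfactors[k])
            mag_e = np.abs(e)
            mag_e[mag_e == 0] = 1.0
            e2 = mags[k] * e / mag_e
            acc += _ifft2c(e2) * np.conj(dfactors[k])
        acc /= len(z_um)
        if smooth_sigma_px > 0:
            acc = ndimage.gaussian_filter(acc.real, smooth_sigma_px) + 1j * (
                ndimage.gaussian_filter(acc.imag, smooth_sigma_px)
            )
        phase = np.angle(acc)
        pupil = aperture * np.exp(1j * phase)

        model = _forward_stack(phase, aperture, defocus)
        err = float(np.sqrt(np.mean((model - meas) ** 2)) / np.sqrt(np.mean(meas**2)))
        if err < best_err * (1.0 - tol):
            best_err, best_phase = err, phase
            stall = 0
        else:
            stall += 1
            if stall >= 10:
                break
    if not np.isfinite(best_err):
        raise RuntimeError("phase retrieval stagnated without converging")

    if template_range_um is None:
        template_range_um = (float(z_um.min()), float(z_um.max()))
    px = template_pixel_nm or config.effective_pixel_nm
    tz = np.arange(template_range_um[0], template_range_um[1] + template_step_um / 2,
                   template_step_um)
    cal = TetrapodCalibration(
        pupil_phase=best_phase,
        grid=grid,
        config=config,
        wavelength_nm=config.emission_wavelength_nm,
        z_range_um=template_range_um,
        image_error=best_err,
        template_z_um=tz,
        templates=None,
        template_pixel_nm=px,
    )
    cal.templates = render_templates(cal, tz, px, template_pixels)
    cal.fine_templates = render_templates(
        cal, tz, px / cal.oversample, template_pixels * cal.oversample
    )
    return cal


def forward_model(
    cal: TetrapodCalibration, z_um: np.ndarray, normalize: bool = True
) -> np.ndarray:
    """Native-grid intensity stack predicted by the retrieved pupil."""
    grid, config = cal.grid, cal.config
    defocus = np.stack([optics.defocus_phase(grid, config, z) for z in z_um])
    return _forward_stack(cal.pupil_phase, grid.aperture(), defocus, norm=normalize)


def render_templates(
    cal: TetrapodCalibration,
    z_um: np.ndarray,
    pixel_nm: float,
    n_pixels: int,
) -> np.ndarray:
    """Camera-grid template stack from the retrieved pupil (unit-sum planes)."""
    clear = optics.PhaseMask(
        kind="clear", phase=np.zeros_like(cal.pupil_phase),
        nominal_range_um=max(abs(z) for z in cal.z_range_um) or 1.0,
        design_wavelength_nm=cal.wavelength_nm, grid=cal.grid,
    )
    out = np.stack(
        [
            optics.psf_at(
                clear, z, cal.config, pixel_nm, n_pixels,
                pupil_phase=cal.pupil_phase, max_clip=None,
            )
            for z in z_um
        ]
    )
    return out / out.sum(axis=(1, 2), keepdims=True)


def _parabolic(ym: float, y0: float, yp: float) -> float:
    denom = ym - 2.0 * y0 + yp
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (ym - yp) / denom, -1.0, 1.0))


def track_fiducial(
    frame_photons: np.ndarray,
    cal: TetrapodCalibration,
    previous_nm: tuple[float, float, float] | None = None,
    z_window_um: float = 0.6,
    corr_floor: float = 0.35,
) -> dict:
    """Locate one tetrapod fiducial in a photon-unit frame.

    z maximizes the normalized cross-correlation against the template
    stack (parabolic sub-step interpolation); x, y come from the
    sub-pixel correlation peak of the best template.  With a previous
    position, only templates within ``z_window_um`` are searched.
    Returns a record with ``quality`` = peak correlation; a peak below
    ``corr_floor`` flags a dropout (NaN position).
    """
    from skimage.feature import match_template

    tz = cal.template_z_um
    if previous_nm is not None and np.isfinite(previous_nm[2]):
        zc = previous_nm[2] * 1e-3
        sel = np.flatnonzero(np.abs(tz - zc) <= z_window_um)
        if sel.size < 3:
            sel = np.arange(len(tz))
    else:
        sel = np.arange(len(tz))

    npx = frame_photons.shape[0]
    best = (-np.inf, None, None)
    scores = np.full(len(tz), np.nan)
    for k in sel:
        cc = match_template(frame_photons, cal.templates[k], pad_input=True)
        iy, ix = np.unravel_index(np.argmax(cc), cc.shape)
        scores[k] = cc[iy, ix]
        if scores[k] > best[0]:
            best = (scores[k], k, (iy, ix))
    peak, kbest, (iy, ix) = best
    if peak < corr_floor:
        return {"x_nm": np.nan, "y_nm": np.nan, "z_nm": np.nan,
                "quality": float(peak), "dropout": True}

    # crop the frame to the template footprint at the integer peak
    nt = cal.templates.shape[1]
    h = nt // 2
    y0 = int(np.clip(iy - h, 0, npx - nt))
    x0 = int(np.clip(ix - h, 0, npx - nt))
    crop = frame_photons[y0 : y0 + nt, x0 : x0 + nt]

    # continuous (x, y, z) refinement: maximize the Pearson correlation of
    # the crop against z-interpolated, sub-pixel-shifted fine templates
    from scipy import optimize

    cv = crop.ravel() - crop.mean()
    cnorm = np.linalg.norm(cv)

    def neg_corr(p: np.ndarray) -> float:
        t = cal.interp_template(p[0], p[1], p[2]).ravel()
        t = t - t.mean()
        denom = np.linalg.norm(t) * cnorm
        return -float(t @ cv / denom) if denom > 0 else 0.0

    # when the crop was clipped at a frame border the bead is off-center in
    # it; start the optimizer at the known integer offset
    p0 = np.array([float(ix - (x0 + h)), float(iy - (y0 + h)), tz[kbest]])
    sol = optimize.minimize(
        neg_corr, p0, method="Nelder-Mead",
        options=dict(
            xatol=1e-3, fatol=1e-8, maxiter=400,
            initial_simplex=p0 + np.array(
                [[0, 0, 0], [0.3, 0, 0], [0, 0.3, 0], [0, 0, 0.04]]
            ),
        ),
    )
    dx, dy, z_um = sol.x
    quality = -float(sol.fun)
    x_nm = (x0 + h + dx - npx // 2) * cal.template_pixel_nm
    y_nm = (y0 + h + dy - npx // 2) * cal.template_pixel_nm
    return {"x_nm": float(x_nm), "y_nm": float(y_nm), "z_nm": float(z_um * 1e3),
            "quality": quality, "dropout": False}


@dataclass
class FiducialTrack:
    """Time-ordered fiducial positions from the interleaved frames."""

    table: pd.DataFrame  # frame, x_nm, y_nm, z_nm, quality, dropout

    def __post_init__(self) -> None:
        if not self.table["frame"].is_monotonic_increasing:
            raise ValueError("track must be time-ordered")


def track_stream(stream, cal: TetrapodCalibration,
                 offset_map: np.ndarray | None = None) -> FiducialTrack:
    """Track the fiducial through every fiducial frame of a stream.

    Dropouts inherit the last good position as the search seed; their
    coordinates are linearly interpolated afterwards.
    """
    from tilt3d.scope import counts_to_photons

    rows = []
    prev = None
    prev_focal = None
    for f in range(stream.n_frames):
        if stream.roles[f] != "fiducial":
            continue
        focal = stream.focal_z_um[f]
        if prev is not None and prev_focal is not None and focal != prev_focal:
            # the bead's template-relative z shifts when the focal plane moves
            prev = (prev[0], prev[1], prev[2] - (focal - prev_focal) * 1e3)
        ph = counts_to_photons(stream.frames[f], stream.camera, offset_map)
        rec = track_fiducial(ph, cal, previous_nm=prev)
        # template z is relative to the focal plane: store absolute height
        if not rec["dropout"]:
            rec_abs = rec["z_nm"] + focal * 1e3
            prev = (rec["x_nm"], rec["y_nm"], rec["z_nm"])
            prev_focal = focal
        else:
            rec_abs = np.nan
        rows.append({"frame": f, "x_nm": rec["x_nm"], "y_nm": rec["y_nm"],
                     "z_nm": rec_abs, "quality": rec["quality"],
                     "dropout": rec["dropout"]})
    df = pd.DataFrame(rows)
    for c in ("x_nm", "y_nm", "z_nm"):
        df[c] = df[c].interpolate(limit_direction="both")
    return FiducialTrack(df)


def track_quality(track: FiducialTrack, jump_threshold_nm: float = 250.0) -> dict:
    """Dropout fraction, per-axis detrended robust scatter, jump flags."""
    t = track.table
    if len(t) < 2:
        raise ValueError("need >= 2 track points")
    out = {"n_points": len(t), "dropout_fraction": float(t["dropout"].mean())}
    frames = t["frame"].to_numpy(dtype=float)
    jumps = []
    for c in ("x_nm", "y_nm", "z_nm"):
        v = t[c].to_numpy(dtype=float)
        fit = np.polynomial.Polynomial.fit(frames, v, 1)(frames)
        resid = v - fit
        mad = np.median(np.abs(resid - np.median(resid)))
        out[f"scatter_{c}"] = float(1.4826 * mad)
        step = np.abs(np.diff(v))
        jumps.extend(int(t["frame"].iloc[i + 1]) for i in np.flatnonzero(step > jump_threshold_nm))
    out["jump_frames"] = sorted(set(jumps))
    return out
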