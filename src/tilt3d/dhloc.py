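"""Double-helix single-molecule localization.

The double-helix PSF shows two lobes; the midpoint of the lobe pair
reports the lateral (x, y) position and the angle of the line connecting
the lobe centers encodes the axial position z.  The estimator is a
least-squares double-Gaussian fit (two isotropic Gaussians plus constant
background), which works throughout the sample because the engineered
pupil phase dominates any depth aberration.

Pipeline: ``detect_candidates`` (double-Gaussian matched filter over trial
angles) -> ``fit_double_gaussian`` per ROI -> ``lobe_pair_to_xyz`` using an
angle-z calibration from ``calibrate_dh`` -> ``filter_localizations``.

Localization tables are pandas DataFrames with columns
``frame, x_nm, y_nm, z_nm, photons, background, angle_deg, separation_nm,
asymmetry, residual, slice`` (one row per accepted emitter).  Angles are
degrees modulo 180 in the package-wide frame convention (array row = +y,
column = +x), with the z=0 lobe orientation as reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, signal

from tilt3d import optics

__all__ = [
    "DHCalibration",
    "FitResult",
    "FilterPolicy",
    "detect_candidates",
    "fit_double_gaussian",
    "calibrate_dh",
    "lobe_pair_to_xyz",
    "localize_stream",
    "filter_localizations",
    "empirical_precision",
]


@dataclass
class FitResult:
    """Converged double-Gaussian parameters for one ROI (nm, ROI-centered)."""

    x1: float
    y1: float
    x2: float
    y2: float
    a1: float
    a2: float
    sigma_nm: float
    background: float
    residual: float
    converged: bool

    @property
    def midpoint(self) -> tuple[float, float]:
        return (0.5 * (self.x1 + self.x2), 0.5 * (self.y1 + self.y2))

    @property
    def angle_deg(self) -> float:
        return float(np.degrees(np.arctan2(self.y1 - self.y2, self.x1 - self.x2)) % 180.0)

    @property
    def separation_nm(self) -> float:
        return float(np.hypot(self.x1 - self.x2, self.y1 - self.y2))

    @property
    def asymmetry(self) -> float:
        lo = min(self.a1, self.a2)
        return float(max(self.a1, self.a2) / lo) if lo > 0 else float("inf")


@dataclass
class DHCalibration:
    """Angle-vs-z calibration for a double-helix mask.

    ``z_nm`` / ``angle_deg`` / ``separation_nm`` are the per-plane tables
    from a bead z-scan; ``poly`` the fitted z->angle polynomial;
    ``z_valid_nm`` the maximal strictly monotone interval around focus;
    ``mid_offset_nm`` the per-z lateral wobble of the lobe midpoint,
    subtracted from fitted midpoints.
    """

    z_nm: np.ndarray
    angle_deg: np.ndarray
    separation_nm: np.ndarray
    poly: np.polynomial.Polynomial
    z_valid_nm: tuple[float, float]
    ref_angle_deg: float
    mid_offset_nm: np.ndarray  # (n, 2) x/y midpoint offset per table z
    pixel_nm: float = 160.0
    _zgrid: np.ndarray = dc_field(default=None, repr=False)
    _agrid: np.ndarray = dc_field(default=None, repr=False)

    def __post_init__(self) -> None:
        z0, z1 = self.z_valid_nm
        if z1 - z0 < 0:
            raise ValueError("invalid calibration range")
        self._zgrid = np.linspace(z0, z1, 2048)
        self._agrid = self.poly(self._zgrid)

    @property
    def mean_separation_nm(self) -> float:
        return float(np.mean(self.separation_nm))

    def z_from_angle(self, angle_deg: float, clip: bool = False) -> float:
        """Invert the calibrated angle polynomial for a measured (raw) angle.

        The z=0 reference orientation is subtracted and the result is
        wrapped on the half-turn circle into the calibrated interval;
        angles outside the monotone range give NaN, or the nearest range
        edge when ``clip`` is set (useful as a refinement seed).
        """
        a = self._agrid
        lo, hi = (a[0], a[-1]) if a[0] < a[-1] else (a[-1], a[0])
        rel = angle_deg - self.ref_angle_deg
        cand = rel + 180.0 * np.round((0.5 * (lo + hi) - rel) / 180.0)
        if not lo <= cand <= hi:
            if clip:
                cand = min(max(cand, lo), hi)
            else:
                return float("nan")
        if a[0] < a[-1]:
            return float(np.interp(cand, a, self._zgrid))
        return float(np.interp(cand, a[::-1], self._zgrid[::-1]))

    def xy_offset(self, z_nm: float) -> tuple[float, float]:
        ox = np.interp(z_nm, self.z_nm, self.mid_offset_nm[:, 0])
        oy = np.interp(z_nm, self.z_nm, self.mid_offset_nm[:, 1])
        return float(ox), float(oy)


# ---------------------------------------------------------------------------
# detection

def _lobe_kernel(sep_px: float, angle_deg: float, sigma_px: float, half: int) -> np.ndarray:
    c = np.arange(-half, half + 1)
    x, y = np.meshgrid(c, c)
    th = np.deg2rad(angle_deg)
    k = np.zeros_like(x, dtype=float)
    for s in (+0.5, -0.5):
        cx, cy = s * sep_px * np.cos(th), s * sep_px * np.sin(th)
        k += np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * sigma_px**2))
    return k / k.sum()


def detect_candidates(
    frame_photons: np.ndarray,
    expected_sep_nm: float,
    pixel_nm: float,
    threshold: float | None = None,
    n_angles: int = 6,
    sigma_px: float = 1.1,
    roi_half: int | None = None,
) -> list[tuple[int, int]]:
    """Find lobe-pair midpoints with a rotating matched filter.

    Convolves the frame with two-displaced-Gaussian kernels over
    ``n_angles`` trial orientations, takes the per-pixel max response, and
    returns local maxima above threshold as (row, col) ROI centers.
    ``threshold`` defaults to median + 6 robust sigma of the response.
    """
    from skimage.feature import peak_local_max

    sep_px = expected_sep_nm / pixel_nm
    half = int(np.ceil(sep_px)) + 3
    f = frame_photons - np.median(frame_photons)
    resp = None
    for ang in np.linspace(0.0, 180.0, n_angles, endpoint=False):
        k = _lobe_kernel(sep_px, ang, sigma_px, half)
        r = signal.fftconvolve(f, k[::-1, ::-1], mode="same")
        resp = r if resp is None else np.maximum(resp, r)
    if threshold is None:
        mad = np.median(np.abs(resp - np.median(resp)))
        threshold = np.median(resp) + 6.0 * 1.4826 * mad
    min_dist = max(2, int(round(1.5 * sep_px)))
    peaks = peak_local_max(resp, min_distance=min_dist, threshold_abs=threshold)
    return [tuple(p) for p in peaks]


# ---------------------------------------------------------------------------
# fitting

def _double_gauss(params: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    x1, y1, x2, y2, a1, a2, sig, bg = params
    g1 = a1 * np.exp(-((x - x1) ** 2 + (y - y1) ** 2) / (2 * sig**2))
    g2 = a2 * np.exp(-((x - x2) ** 2 + (y - y2) ** 2) / (2 * sig**2))
    return bg + g1 + g2


def fit_double_gaussian(
    roi: np.ndarray,
    pixel_nm: float,
    sep_guess_nm: float = 850.0,
    angle_guess_deg: float | None = None,
    sigma_guess_nm: float = 170.0,
    weighting: str = "none",
    min_lobe_sep_nm: float | None = None,
) -> FitResult:
    """Least-squares fit of two isotropic Gaussians + constant background.

    Coordinates are nm relative to the ROI center (row = +y).
    ``weighting='poisson'`` divides residuals by sqrt(max(data, 1)) for an
    approximate maximum-likelihood fit at low counts.  Fits whose lobes
    collapse closer than one pixel are reported unconverged.
    """
    n = roi.shape[0]
    if roi.size < 9:
        raise ValueError("ROI smaller than the model parameter count")
    c = (np.arange(n) - n // 2) * pixel_nm
    x, y = np.meshgrid(c, c)
    bg0 = float(np.percentile(roi, 20))
    amp0 = max(float(roi.max() - bg0), 1e-3)

    if angle_guess_deg is None:
        sm = ndimage.gaussian_filter(roi - bg0, 1.0)
        iy, ix = np.unravel_index(np.argmax(sm), sm.shape)
        blocked = sm.copy()
        r_ex = max(2, int(0.6 * sep_guess_nm / pixel_nm))
        yy, xx = np.ogrid[:n, :n]
        blocked[(yy - iy) ** 2 + (xx - ix) ** 2 < r_ex**2] = -np.inf
        jy, jx = np.unravel_index(np.argmax(blocked), blocked.shape)
        p1 = (c[ix], c[iy])
        p2 = (c[jx], c[jy])
    else:
        th = np.deg2rad(angle_guess_deg)
        dx, dy = 0.5 * sep_guess_nm * np.cos(th), 0.5 * sep_guess_nm * np.sin(th)
        p1, p2 = (dx, dy), (-dx, -dy)

    p0 = np.array(
        [p1[0], p1[1], p2[0], p2[1], amp0, amp0, sigma_guess_nm, max(bg0, 0.0)]
    )
    half_nm = c[-1]
    lb = [-half_nm, -half_nm, -half_nm, -half_nm, 0.0, 0.0, pixel_nm * 0.3, 0.0]
    ub = [half_nm, half_nm, half_nm, half_nm, np.inf, np.inf, pixel_nm * 4.0, np.inf]

    def solve(p_start, w):
        def resid(p):
            return ((_double_gauss(p, x, y) - roi) / w).ravel()

        sol = optimize.least_squares(resid, p_start, bounds=(lb, ub), method="trf",
                                     xtol=1e-10, ftol=1e-10)
        return sol.success, sol.x

    try:
        ok, p = solve(p0, 1.0)
        if weighting == "poisson" and ok:
            # iteratively reweighted least squares with model-based Poisson
            # variances: unbiased (unlike data weighting) and close to MLE
            for _ in range(2):
                w = np.sqrt(np.maximum(_double_gauss(p, x, y), 0.25))
                ok, p = solve(p, w)
    except Exception:
        ok, p = False, p0
    rms = float(np.sqrt(np.mean((_double_gauss(p, x, y) - roi).ravel() ** 2)))
    scale = float(max(p[4], p[5], 1e-9))
    fit = FitResult(
        x1=p[0], y1=p[1], x2=p[2], y2=p[3], a1=p[4], a2=p[5],
        sigma_nm=p[6], background=p[7], residual=rms / scale, converged=bool(ok),
    )
    min_sep = pixel_nm if min_lobe_sep_nm is None else min_lobe_sep_nm
    if fit.separation_nm < min_sep:
        fit.converged = False
    return fit


# Frames follow the row = +y, col = +x convention throughout the package, so
# fitted coordinates are used as-is.


# ---------------------------------------------------------------------------
# calibration

def calibrate_dh(
    stack: optics.PSFStack,
    poly_degree: int = 5,
    min_valid_nm: float = 1000.0,
) -> DHCalibration:
    """Build an angle/separation-vs-z calibration from a single-bead z-scan.

    Fits every plane with the double-Gaussian estimator, unwraps the lobe
    angle on the half-turn circle, fits a polynomial, and keeps the maximal
    strictly monotone interval around focus as the valid range.  Raises if
    that interval is shorter than ``min_valid_nm``.
    """
    order = np.argsort(stack.z_um)
    z_nm = stack.z_um[order] * 1e3
    fits = []
    for idx in order:
        plane = stack.images[idx]
        fit = fit_double_gaussian(plane, stack.pixel_nm)
        if not fit.converged:
            raise ValueError(f"calibration plane at z={stack.z_um[idx]} um failed to fit")
        fits.append(fit)
    ang = np.array([f.angle_deg for f in fits])
    ang = np.rad2deg(np.unwrap(np.deg2rad(2.0 * ang))) / 2.0
    sep = np.array([f.separation_nm for f in fits])
    mids = np.array([f.midpoint for f in fits])

    d = np.diff(ang)
    if not (np.all(d > 0) or np.all(d < 0)):
        # keep the longest monotone stretch containing the focus plane
        sign = np.sign(np.median(d))
        good = np.flatnonzero(np.sign(d) == sign)
        runs = np.split(good, np.where(np.diff(good) > 1)[0] + 1)
        i0 = int(np.argmin(np.abs(z_nm)))
        run = next((r for r in runs if r[0] <= i0 <= r[-1] + 1), max(runs, key=len))
        sl = slice(run[0], run[-1] + 2)
        z_nm, ang, sep, mids = z_nm[sl], ang[sl], sep[sl], mids[sl]

    poly = np.polynomial.Polynomial.fit(z_nm, ang, deg=poly_degree).convert()
    zg = np.linspace(z_nm[0], z_nm[-1], 4096)
    da = np.diff(poly(zg))
    sign = np.sign(np.median(da))
    bad = np.flatnonzero(np.sign(da) != sign)
    zlo, zhi = z_nm[0], z_nm[-1]
    i0 = np.argmin(np.abs(zg))
    if bad.size:
        left = bad[bad < i0]
        right = bad[bad >= i0]
        if left.size:
            zlo = zg[left[-1] + 1]
        if right.size:
            zhi = zg[right[0]]
    if zhi - zlo < min_valid_nm:
        raise ValueError(
            f"monotone angle range {zhi - zlo:.0f} nm shorter than {min_valid_nm:.0f} nm"
        )
    ref = float(poly(0.0))
    mid0 = mids[np.argmin(np.abs(z_nm))]
    return DHCalibration(
        z_nm=z_nm,
        angle_deg=ang - ref,
        separation_nm=sep,
        poly=poly - ref,
        z_valid_nm=(float(zlo), float(zhi)),
        ref_angle_deg=ref,
        mid_offset_nm=mids - mid0,
        pixel_nm=stack.pixel_nm,
    )


# ---------------------------------------------------------------------------
# inversion and the frame pipeline

def lobe_pair_to_xyz(
    fit: FitResult,
    calib: DHCalibration,
    roi_center_nm: tuple[float, float] = (0.0, 0.0),
    frame: int = -1,
    slice_index: int = 0,
) -> dict:
    """Convert a converged lobe-pair fit to a localization record.

    xy is the lobe midpoint (minus the calibrated per-z wobble), z inverts
    the angle polynomial; photons integrate both Gaussians.  Records whose
    angle falls outside the calibrated monotone range carry
    ``reason='z_out_of_range'`` and NaN z.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    z = calib.z_from_angle(fit.angle_deg - 0.0)
    reason = ""
    if np.isnan(z):
        reason = "z_out_of_range"
        ox = oy = 0.0
    else:
        ox, oy = calib.xy_offset(z)
    mx, my = fit.midpoint
    photons = (fit.a1 + fit.a2) * 2.0 * np.pi * fit.sigma_nm**2 / calib.pixel_nm**2
    return {
        "frame": frame,
        "x_nm": roi_center_nm[0] + mx - ox,
        "y_nm": roi_center_nm[1] + my - oy,
        "z_nm": z,
        "photons": photons,
        "background": fit.background,
        "angle_deg": fit.angle_deg,
        "separation_nm": fit.separation_nm,
        "asymmetry": fit.asymmetry,
        "residual": fit.residual,
        "slice": slice_index,
        "reason": reason,
    }


def localize_frame(
    frame_photons: np.ndarray,
    calib: DHCalibration,
    pixel_nm: float,
    frame_index: int = -1,
    slice_index: int = 0,
    roi_half: int = 12,
    threshold: float | None = None,
    weighting: str = "none",
    refine: "TemplateModel | None" = None,
) -> list[dict]:
    """Detect and fit all double-helix emitters in one photon-unit frame.

    With ``refine`` set, each double-Gaussian estimate seeds a Poisson
    maximum-likelihood polish against the rendered PSF model (out-of-range
    angles are seeded at the nearest calibrated edge and re-estimated by
    the likelihood).
    """
    npx = frame_photons.shape[0]
    peaks = detect_candidates(
        frame_photons, calib.mean_separation_nm, pixel_nm, threshold=threshold
    )
    out = []
    for iy, ix in peaks:
        if not (roi_half <= iy < npx - roi_half and roi_half <= ix < npx - roi_half):
            continue
        roi = frame_photons[
            iy - roi_half : iy + roi_half + 1, ix - roi_half : ix + roi_half + 1
        ]
        fit = fit_double_gaussian(
            roi, pixel_nm, sep_guess_nm=calib.mean_separation_nm, weighting=weighting
        )
        if not fit.converged:
            continue
        cx = (ix - npx // 2) * pixel_nm
        cy = (iy - npx // 2) * pixel_nm
        rec = lobe_pair_to_xyz(fit, calib, (cx, cy), frame_index, slice_index)
        if refine is not None:
            z_seed = rec["z_nm"]
            if np.isnan(z_seed):
                z_seed = calib.z_from_angle(fit.angle_deg, clip=True)
            x, y, zr, nph, bgr, ok = refine.refine(
                roi, rec["x_nm"] - cx, rec["y_nm"] - cy, z_seed,
                rec["photons"], rec["background"],
            )
            if not ok:
                continue
            z_edge = 0.005 * (refine.z_um[-1] - refine.z_um[0]) * 1e3
            at_edge = (
                zr < refine.z_um[0] * 1e3 + z_edge or zr > refine.z_um[-1] * 1e3 - z_edge
            )
            rec.update(
                x_nm=cx + x, y_nm=cy + y, z_nm=float("nan") if at_edge else zr,
                photons=nph, background=bgr,
                reason="z_out_of_range" if at_edge else rec["reason"],
            )
        out.append(rec)
    return out


def localize_stream(
    stream,
    calib: DHCalibration,
    offset_map: np.ndarray | None = None,
    threshold: float | None = None,
    weighting: str = "none",
    roi_half: int = 12,
    refine: "TemplateModel | None" = None,
) -> pd.DataFrame:
    """Localize every SM frame of a simulated stream.

    Dark-subtracts and photon-converts each frame, then runs detection and
    fitting.  z is reported in absolute µm-scale nm by adding the per-frame
    focal plane, so slices and feedback moves line up.
    """
    from tilt3d.scope import counts_to_photons

    rows = []
    for f in range(stream.n_frames):
        if stream.roles[f] != "sm":
            continue
        ph = counts_to_photons(stream.frames[f], stream.camera, offset_map)
        recs = localize_frame(
            ph, calib, stream.pixel_nm, f, int(stream.slice_index[f]),
            roi_half=roi_half, threshold=threshold, weighting=weighting,
            refine=refine,
        )
        for r in recs:
            if not np.isnan(r["z_nm"]):
                r["z_abs_nm"] = r["z_nm"] + stream.focal_z_um[f] * 1e3
            else:
                r["z_abs_nm"] = float("nan")
            rows.append(r)
    cols = ["frame", "x_nm", "y_nm", "z_nm", "z_abs_nm", "photons", "background",
            "angle_deg", "separation_nm", "asymmetry", "residual", "slice", "reason"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# template maximum-likelihood refinement

class TemplateModel:
    """Pixelated PSF model on a fine z grid for likelihood refinement.

    Renders the mask's PSF every ``step_um`` across [z_min, z_max] once;
    ``expected`` then produces the model image for arbitrary (x, y, z) by
    linear z interpolation and cubic-spline sub-pixel shifting.  Used by
    the optional maximum-likelihood polish after the double-Gaussian fit.
    """

    def __init__(
        self,
        mask: optics.PhaseMask,
        config: optics.OpticalConfig,
        z_min_um: float,
        z_max_um: float,
        step_um: float = 0.02,
        n_pixels: int = 25,
        pixel_nm: float | None = None,
        oversample: int = 2,
    ) -> None:
        self.pixel_nm = config.effective_pixel_nm if pixel_nm is None else pixel_nm
        self.z_um = np.arange(z_min_um, z_max_um + step_um / 2, step_um)
        self.oversample = oversample
        fine_px = self.pixel_nm / oversample
        n_fine = n_pixels * oversample
        # sub-pixel shifts are applied on an oversampled grid and binned to
        # camera pixels, keeping spline interpolation error well below the
        # localization precision even on the sharp lobe axis
        self.stack = np.stack(
            [
                optics.psf_at(mask, zi, config, fine_px, n_fine, max_clip=None)
                for zi in self.z_um
            ]
        )
        self.n_pixels = n_pixels

    def expected(self, x_nm: float, y_nm: float, z_nm: float,
                 photons: float, bg: float) -> np.ndarray:
        z_um = np.clip(z_nm * 1e-3, self.z_um[0], self.z_um[-1])
        i = min(np.searchsorted(self.z_um, z_um) - 1, len(self.z_um) - 2)
        i = max(i, 0)
        w = (z_um - self.z_um[i]) / (self.z_um[i + 1] - self.z_um[i])
        plane = (1.0 - w) * self.stack[i] + w * self.stack[i + 1]
        os = self.oversample
        fine_px = self.pixel_nm / os
        shifted = ndimage.shift(
            plane, (y_nm / fine_px, x_nm / fine_px),
            order=3, mode="nearest", prefilter=True,
        )
        # fine samples at stride ``os`` coincide with camera pixel centers,
        # matching the point-sampled pixel convention used in rendering
        off = len(plane) // 2 - os * (self.n_pixels // 2)
        binned = shifted[off::os, off::os][: self.n_pixels, : self.n_pixels]
        return photons * np.clip(binned, 0.0, None) + bg

    def refine(
        self, roi: np.ndarray, x0: float, y0: float, z0: float,
        photons0: float, bg0: float,
    ) -> tuple[float, float, float, float, float, bool]:
        """Poisson maximum-likelihood polish of one localization.

        Minimizes sum(mu - d log mu) over (x, y, z, photons, background)
        starting from the double-Gaussian estimate.
        """
        d = roi.ravel()

        def nll(p):
            mu = self.expected(p[0], p[1], p[2], abs(p[3]), abs(p[4])).ravel()
            mu = np.maximum(mu, 1e-9)
            return float(np.sum(mu - d * np.log(mu)))

        p0 = np.array([x0, y0, z0, photons0, max(bg0, 0.1)])
        sol = optimize.minimize(
            nll, p0, method="Nelder-Mead",
            options=dict(xatol=0.05, fatol=1e-3, maxiter=1500),
        )
        x, y, z, n, b = sol.x
        return float(x), float(y), float(z), float(abs(n)), float(abs(b)), bool(sol.success)


# ---------------------------------------------------------------------------
# quality filtering and precision

@dataclass(frozen=True)
class FilterPolicy:
    """Quality thresholds; None disables a test."""

    max_residual: float | None = 0.25
    max_asymmetry: float | None = 2.5
    max_separation_dev: float | None = 0.20  # fractional, vs calibration
    min_photons: float | None = 200.0
    require_z: bool = True
    max_abs_z_nm: float | None = None  # trim the working-range edges


def filter_localizations(
    locs: pd.DataFrame,
    policy: FilterPolicy | None = None,
    calib: DHCalibration | None = None,
) -> pd.DataFrame:
    """Drop records failing the policy; each drop is tagged in ``reason``.

    Returns the surviving rows; the input frame is annotated in place with
    the reason of the first failing test.
    """
    if policy is None:
        policy = FilterPolicy()
    keep = np.ones(len(locs), dtype=bool)
    reasons = locs["reason"].astype(str).to_numpy(copy=True)

    def mark(bad: np.ndarray, tag: str) -> None:
        nonlocal keep
        newly = bad & keep
        reasons[newly] = tag
        keep &= ~bad

    if policy.require_z:
        mark(locs["z_nm"].isna().to_numpy(), "z_out_of_range")
    if policy.max_abs_z_nm is not None:
        z = np.nan_to_num(locs["z_nm"].to_numpy(), nan=np.inf)
        mark(np.abs(z) > policy.max_abs_z_nm, "z_range_trim")
    if policy.max_residual is not None:
        mark(locs["residual"].to_numpy() > policy.max_residual, "residual")
    if policy.max_asymmetry is not None:
        mark(locs["asymmetry"].to_numpy() > policy.max_asymmetry, "asymmetry")
    if policy.max_separation_dev is not None and calib is not None:
        ref = np.interp(
            np.nan_to_num(locs["z_nm"].to_numpy()), calib.z_nm, calib.separation_nm
        )
        dev = np.abs(locs["separation_nm"].to_numpy() - ref) / ref
        mark(dev > policy.max_separation_dev, "separation")
    if policy.min_photons is not None:
        mark(locs["photons"].to_numpy() < policy.min_photons, "photons")
    locs = locs.copy()
    locs["reason"] = reasons
    return locs[keep].reset_index(drop=True)


def empirical_precision(locs: pd.DataFrame, detrend: bool = True) -> dict[str, float]:
    """Per-axis scatter of repeated localizations of one static emitter.

    Optionally removes a linear time trend (residual drift) per axis before
    taking the standard deviation.  Requires >= 20 repeats.
    """
    if len(locs) < 20:
        raise ValueError("need >= 20 repeated localizations")
    out = {}
    t = locs["frame"].to_numpy(dtype=float)
    for axis, col in (("x_nm", "x_nm"), ("y_nm", "y_nm"),
                      ("z_nm", "z_abs_nm" if "z_abs_nm" in locs else "z_nm")):
        v = locs[col].to_numpy(dtype=float)
        if detrend and len(np.unique(t)) > 2:
            v = v - np.polynomial.Polynomial.fit(t, v, 1)(t)
        out[axis] = float(np.std(v, ddof=1))
    return out
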