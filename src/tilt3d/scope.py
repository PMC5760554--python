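"""Synthetic-microscope frame-stream generator.

Produces EM-CCD image stacks of blinking emitters on 3D phantom structures
under epi or tilted light-sheet illumination, with engineered PSFs per
frame role, slow 3D stage drift, and the interleaved acquisition schedule
used for fiducial-corrected super-resolution runs: single-molecule (SM)
frames interleaved with tetrapod fiducial frames every Nth frame and
optional UV reactivation frames late in the run.

The generator is the fixture factory for the analysis pipeline: every
stream carries a ground-truth log (emitter states, true drifted positions,
expected photon counts) from which the pre-noise image of any frame can be
re-rendered bit-for-bit.

Conventions: lateral positions in nm within the field of view (origin at
the field center), axial positions z in µm above the coverslip.  Frame
indices are 1-based in the schedule (frame 20 is the first fiducial frame
for a period of 20), 0-based in arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable

import numpy as np
import pandas as pd

from tilt3d import optics
from tilt3d.illumination import IlluminationField, intensity_at

__all__ = [
    "Phantom",
    "BlinkModel",
    "CameraModel",
    "AcquisitionSchedule",
    "DriftModel",
    "FrameStream",
    "make_phantom",
    "simulate_stream",
    "expected_frame",
    "dark_frames",
    "dark_calibrate",
    "counts_to_photons",
]

_ROI_BY_KIND = {"clear": 16, "double_helix": 32, "tetrapod": 64}


@dataclass
class Phantom:
    """Emitter positions decorating a geometric structure.

    ``positions`` is (N, 3): x, y in nm (field coordinates), z in µm.
    """

    positions: np.ndarray
    kind: str
    params: dict = dc_field(default_factory=dict)

    @property
    def n_emitters(self) -> int:
        return len(self.positions)


def _sample_sphere_surface(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def make_phantom(
    kind: str,
    density_per_um2: float = 50.0,
    seed: int = 0,
    *,
    center_um: tuple[float, float, float] = (0.0, 0.0, 3.0),
    radius_um: float = 2.5,
    thickness_nm: float = 100.0,
    length_um: float = 4.0,
    axis: str = "x",
    positions: np.ndarray | None = None,
) -> Phantom:
    """Sample emitters on a labeled structure.

    Kinds: ``lamina_shell`` (spherical shell of given radius/thickness, the
    nuclear-envelope analogue), ``mito_cylinder`` (hollow cylinder surface,
    outer-membrane analogue), ``bead_field`` / ``points`` (explicit
    positions).  The emitter count is Poisson with mean surface area x
    density; placement is uniform on the surface and deterministic given
    the seed.
    """
    rng = np.random.default_rng(seed)
    cx, cy, cz = center_um
    if kind in ("points", "bead_field"):
        if positions is None:
            raise ValueError(f"{kind} phantom requires explicit positions")
        return Phantom(np.asarray(positions, dtype=float), kind)
    if density_per_um2 <= 0:
        raise ValueError("density must be positive")
    if radius_um <= 0:
        raise ValueError("degenerate geometry: zero radius")
    if kind == "lamina_shell":
        area = 4.0 * np.pi * radius_um**2
        n = rng.poisson(area * density_per_um2)
        u = _sample_sphere_surface(rng, n)
        # labeled-shell radial profile is Gaussian with FWHM = thickness,
        # truncated at +-thickness so all emitters stay near the surface
        sig = thickness_nm / 2.3548
        dr = rng.normal(0.0, sig, n)
        while np.any(np.abs(dr) > thickness_nm):
            bad = np.abs(dr) > thickness_nm
            dr[bad] = rng.normal(0.0, sig, int(bad.sum()))
        r_um = radius_um + dr * 1e-3
        xyz = u * r_um[:, None]
        pos = np.column_stack(
            [
                (cx + xyz[:, 0]) * 1e3,
                (cy + xyz[:, 1]) * 1e3,
                cz + xyz[:, 2],
            ]
        )
        return Phantom(pos, kind, dict(center_um=center_um, radius_um=radius_um,
                                       thickness_nm=thickness_nm))
    if kind == "mito_cylinder":
        radius_nm = radius_um * 1e3
        area = 2.0 * np.pi * radius_um * length_um
        n = rng.poisson(area * density_per_um2)
        phi = rng.uniform(0, 2 * np.pi, n)
        along = rng.uniform(-0.5, 0.5, n) * length_um * 1e3
        r_nm = radius_nm + rng.uniform(-0.5, 0.5, n) * thickness_nm
        if axis == "x":
            x = cx * 1e3 + along
            y = cy * 1e3 + r_nm * np.cos(phi)
            z = cz + r_nm * np.sin(phi) * 1e-3
        else:
            x = cx * 1e3 + r_nm * np.cos(phi)
            y = cy * 1e3 + along
            z = cz + r_nm * np.sin(phi) * 1e-3
        return Phantom(np.column_stack([x, y, z]), kind,
                       dict(center_um=center_um, radius_nm=radius_nm,
                            thickness_nm=thickness_nm, length_um=length_um, axis=axis))
    raise ValueError(f"unknown phantom kind {kind!r}")


@dataclass(frozen=True)
class BlinkModel:
    """Three-state (dark / on / bleached) fluorophore photoswitching.

    Rates are s^-1 and converted to per-frame probabilities with the
    exposure time.  ``reactivation_boost`` multiplies the dark->on rate on
    the frame following a UV reactivation frame.  Defaults give sparse
    active sets compatible with the double-helix footprint.
    """

    on_to_off_rate: float = 10.0
    off_to_on_rate: float = 0.02
    bleach_rate: float = 0.1
    initial_dark_fraction: float = 0.95
    reactivation_boost: float = 20.0

    def __post_init__(self) -> None:
        if min(self.on_to_off_rate, self.off_to_on_rate, self.bleach_rate) < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.initial_dark_fraction <= 1.0:
            raise ValueError("initial dark fraction must be in [0, 1]")


@dataclass(frozen=True)
class CameraModel:
    """EM-CCD noise model: shot noise, gamma-distributed EM gain, read noise."""

    exposure_ms: float = 50.0
    em_gain: float = 186.0
    quantum_efficiency: float = 1.0
    read_noise_e: float = 3.0
    offset_counts: float = 100.0
    e_per_count: float = 12.0
    n_dark_frames: int = 300

    def __post_init__(self) -> None:
        if self.em_gain < 1:
            raise ValueError("EM gain must be >= 1")
        if self.exposure_ms <= 0:
            raise ValueError("exposure must be positive")


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Interleaved SM / fiducial / reactivation frame plan per slice.

    1-based within the run: every ``fiducial_period``-th frame images the
    fiducial channel; after ``reactivation_start`` frames, every
    ``reactivation_period``-th frame is a UV reactivation frame (taking
    precedence over the fiducial role on coincidence).
    """

    fiducial_period: int = 20
    reactivation_period: int = 100
    reactivation_start: int = 10000
    slices: tuple[tuple[float, float], ...] = ((0.0, 3.0),)  # (sheet offset, focal z) µm
    frames_per_slice: int = 200

    def __post_init__(self) -> None:
        if self.fiducial_period < 1 or self.reactivation_period < 1:
            raise ValueError("periods must be >= 1")
        if not self.slices:
            raise ValueError("need at least one slice")

    def roles(self) -> list[str]:
        out = []
        for _ in self.slices:
            for i in range(1, self.frames_per_slice + 1):
                if i > self.reactivation_start and i % self.reactivation_period == 0:
                    out.append("reactivation")
                elif i % self.fiducial_period == 0:
                    out.append("fiducial")
                else:
                    out.append("sm")
        return out

    def slice_of_frame(self) -> np.ndarray:
        return np.repeat(np.arange(len(self.slices)), self.frames_per_slice)


@dataclass(frozen=True)
class DriftModel:
    """Slow 3D stage drift: linear ramp plus an optional random walk (nm)."""

    linear_nm_per_frame: tuple[float, float, float] = (0.0, 0.0, 0.0)
    random_walk_nm: float = 0.0

    def trace(self, n_frames: int, rng: np.random.Generator) -> np.ndarray:
        t = np.arange(n_frames)[:, None]
        drift = t * np.asarray(self.linear_nm_per_frame)[None, :]
        if self.random_walk_nm > 0:
            steps = rng.normal(0.0, self.random_walk_nm, size=(n_frames, 3))
            steps[0] = 0.0
            drift = drift + np.cumsum(steps, axis=0)
        return drift


@dataclass
class FrameStream:
    """Simulated acquisition: frames, per-frame roles, and ground truth."""

    frames: np.ndarray  # (n, y, x) uint16 counts
    roles: list[str]
    slice_index: np.ndarray
    pixel_nm: float
    truth: pd.DataFrame  # per active emitter per frame
    drift_nm: np.ndarray  # (n, 3) applied sample drift
    focal_z_um: np.ndarray  # per-frame focal plane (after any feedback)
    sheet_offset_um: np.ndarray
    camera: CameraModel
    config: optics.OpticalConfig
    masks: dict[str, optics.PhaseMask]
    fiducials_um: np.ndarray  # (m, 3) x nm, y nm, z µm (undrifted)
    fiducial_photons: float
    background_photons: dict[str, float]

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def _add_roi(frame: np.ndarray, roi: np.ndarray, ix: int, iy: int) -> bool:
    """Add ``roi`` centered at pixel (ix, iy); False if fully outside."""
    n = roi.shape[0]
    h = n // 2
    y0, y1 = iy - h, iy - h + n
    x0, x1 = ix - h, ix - h + n
    fy0, fx0 = max(y0, 0), max(x0, 0)
    fy1, fx1 = min(y1, frame.shape[0]), min(x1, frame.shape[1])
    if fy0 >= fy1 or fx0 >= fx1:
        return False
    frame[fy0:fy1, fx0:fx1] += roi[fy0 - y0 : fy1 - y0, fx0 - x0 : fx1 - x0]
    return True


def _render_emitter(
    mask: optics.PhaseMask,
    config: optics.OpticalConfig,
    frame: np.ndarray,
    x_nm: float,
    y_nm: float,
    dz_um: float,
    photons: float,
    pixel_nm: float,
) -> bool:
    """Render one emitter's expected-photon image into ``frame``."""
    if abs(dz_um) > 2.0 * mask.nominal_range_um:
        return False  # far out of range: contributes only a dim wide blur
    npx = frame.shape[0]
    ix = int(round(x_nm / pixel_nm)) + npx // 2
    iy = int(round(y_nm / pixel_nm)) + npx // 2
    sub_x = x_nm - (ix - npx // 2) * pixel_nm
    sub_y = y_nm - (iy - npx // 2) * pixel_nm
    roi_n = _ROI_BY_KIND.get(mask.kind, 32)
    psf = optics.psf_at(
        mask, dz_um, config, pixel_nm, roi_n, shift_nm=(sub_x, sub_y), max_clip=None
    )
    return _add_roi(frame, photons * psf, ix, iy)


def expected_frame(
    stream: FrameStream, frame_idx: int, truth: pd.DataFrame | None = None
) -> np.ndarray:
    """Re-render the noiseless expected-photon image of one frame.

    Uses only the ground-truth log, so it reproduces the pre-noise image
    the simulator drew the Poisson sample from, bit-for-bit.
    """
    log = stream.truth if truth is None else truth
    rows = log[log.frame == frame_idx]
    npx = stream.frames.shape[1]
    img = np.full((npx, npx), stream.background_photons.get(stream.roles[frame_idx], 0.0))
    role = stream.roles[frame_idx]
    mask = stream.masks["fiducial" if role == "fiducial" else "sm"]
    focal = stream.focal_z_um[frame_idx]
    for r in rows.itertuples():
        _render_emitter(
            mask, stream.config, img, r.x_nm, r.y_nm, r.z_um - focal,
            r.photons, stream.pixel_nm,
        )
    return img


def _camera_noise(
    expected_photons: np.ndarray, camera: CameraModel, rng: np.random.Generator
) -> np.ndarray:
    """Photon image -> raw EM-CCD counts (shot, EM-register, read noise)."""
    mu_e = expected_photons * camera.quantum_efficiency
    n_e = rng.poisson(mu_e)
    amplified = np.where(
        n_e > 0, rng.gamma(np.maximum(n_e, 1e-12), camera.em_gain), 0.0
    )
    amplified = amplified + rng.normal(0.0, camera.read_noise_e, size=mu_e.shape)
    counts = amplified / camera.e_per_count + camera.offset_counts
    return np.clip(np.rint(counts), 0, 65535).astype(np.uint16)


def simulate_stream(
    phantom: Phantom,
    blink: BlinkModel | None = None,
    camera: CameraModel | None = None,
    schedule: AcquisitionSchedule | None = None,
    illum: IlluminationField | None = None,
    masks: dict[str, optics.PhaseMask] | None = None,
    drift: DriftModel | None = None,
    seed: int = 0,
    *,
    config: optics.OpticalConfig | None = None,
    fov_um: float = 15.0,
    brightness_photons: float = 3000.0,
    background_sm: float = 5.0,
    fiducials_um: np.ndarray | None = None,
    fiducial_photons: float = 2.0e5,
    background_fiducial: float = 2.0,
    feedback_hook: Callable[[int, np.ndarray], float] | None = None,
) -> FrameStream:
    """Simulate a full interleaved acquisition.

    Per frame: advance blink states (SM frames only; reactivation frames
    boost the dark->on rate of the next frame), compute each active
    emitter's expected photons as brightness x illumination intensity at
    its drifted position, render its PSF at (z - focal plane), add uniform
    background, then apply the EM-CCD noise chain.  ``feedback_hook``, if
    given, is called after every fiducial frame with (frame index, noisy
    frame) and returns a focal-plane correction in µm applied from the
    next frame on (one-period latency, as for a live axial lock).

    Fully deterministic given ``seed``.
    """
    blink = blink or BlinkModel()
    camera = camera or CameraModel()
    schedule = schedule or AcquisitionSchedule()
    illum = illum or IlluminationField(mode="epi")
    config = config or optics.OpticalConfig()
    drift = drift or DriftModel()
    if masks is None:
        masks = {
            "sm": optics.build_mask("double_helix", 2.0, config=config),
            "fiducial": optics.build_mask("tetrapod", 6.0, config=config),
        }
    if fiducials_um is None:
        fiducials_um = np.array([[-5000.0, -5000.0, 0.5]])
    fiducials_um = np.asarray(fiducials_um, dtype=float)

    rng = np.random.default_rng(seed)
    pixel_nm = config.effective_pixel_nm
    npx = int(round(fov_um * 1e3 / pixel_nm))
    roles = schedule.roles()
    slice_of = schedule.slice_of_frame()
    n_frames = len(roles)
    drift_nm = drift.trace(n_frames, rng)

    dt = camera.exposure_ms * 1e-3
    p_on_off = 1.0 - np.exp(-blink.on_to_off_rate * dt)
    p_off_on = 1.0 - np.exp(-blink.off_to_on_rate * dt)
    p_off_on_boost = 1.0 - np.exp(-blink.off_to_on_rate * blink.reactivation_boost * dt)
    p_bleach = 1.0 - np.exp(-blink.bleach_rate * dt)

    n_em = phantom.n_emitters
    state = np.where(rng.random(n_em) < blink.initial_dark_fraction, 0, 1)

    frames = np.empty((n_frames, npx, npx), dtype=np.uint16)
    focal_z = np.empty(n_frames)
    sheet_off = np.empty(n_frames)
    log_rows: list[tuple] = []
    focal_corr = 0.0
    boosted = False

    for f in range(n_frames):
        role = roles[f]
        s_idx = slice_of[f]
        offset, focal_nominal = schedule.slices[s_idx]
        focal = focal_nominal + focal_corr
        focal_z[f] = focal
        sheet_off[f] = offset
        d = drift_nm[f]
        img = np.full((npx, npx), float(background_photons_for(role, background_sm,
                                                               background_fiducial)))
        if role == "sm":
            # transitions resolved at frame start; emitters on for the frame
            u = rng.random(n_em)
            p_up = p_off_on_boost if boosted else p_off_on
            new_on = (state == 0) & (u < p_up)
            to_off = (state == 1) & (u < p_on_off)
            to_bleach = (state == 1) & ~to_off & (u > 1.0 - p_bleach)
            state[new_on] = 1
            state[to_off] = 0
            state[to_bleach] = 2
            boosted = False
            fld = illum.with_offset(offset) if illum.mode == "sheet" else illum
            for i in np.flatnonzero(state == 1):
                x, y, z = phantom.positions[i]
                xd, yd = x + d[0], y + d[1]
                zd = z + d[2] * 1e-3
                inten = float(
                    intensity_at(fld, (xd * 1e-3, yd * 1e-3, zd))
                )
                photons = brightness_photons * inten
                if photons <= 0:
                    continue
                ok = _render_emitter(
                    masks["sm"], config, img, xd, yd, zd - focal, photons, pixel_nm
                )
                if ok:
                    log_rows.append((f, int(i), "sm", xd, yd, zd, photons, s_idx))
        elif role == "fiducial":
            for i, (x, y, z) in enumerate(fiducials_um * [1.0, 1.0, 1.0]):
                xd, yd = x + d[0], y + d[1]
                zd = z + d[2] * 1e-3
                ok = _render_emitter(
                    masks["fiducial"], config, img, xd, yd, zd - focal,
                    fiducial_photons, pixel_nm,
                )
                if ok:
                    log_rows.append((f, -1 - i, "fiducial", xd, yd, zd,
                                     fiducial_photons, s_idx))
        else:  # reactivation frame: UV pulse, nothing imaged in this channel
            boosted = True
        frames[f] = _camera_noise(img, camera, rng)
        if role == "fiducial" and feedback_hook is not None:
            focal_corr += feedback_hook(f, frames[f])

    truth = pd.DataFrame(
        log_rows,
        columns=["frame", "emitter", "role", "x_nm", "y_nm", "z_um", "photons", "slice"],
    )
    return FrameStream(
        frames=frames,
        roles=roles,
        slice_index=slice_of,
        pixel_nm=pixel_nm,
        truth=truth,
        drift_nm=drift_nm,
        focal_z_um=focal_z,
        sheet_offset_um=sheet_off,
        camera=camera,
        config=config,
        masks=masks,
        fiducials_um=fiducials_um,
        fiducial_photons=fiducial_photons,
        background_photons={"sm": background_sm, "fiducial": background_fiducial,
                            "reactivation": 0.0},
    )


def background_photons_for(role: str, bg_sm: float, bg_fid: float) -> float:
    return {"sm": bg_sm, "fiducial": bg_fid, "reactivation": 0.0}[role]


# ---------------------------------------------------------------------------
# camera calibration

def dark_frames(
    camera: CameraModel, n_frames: int | None = None, shape: tuple[int, int] = (94, 94),
    seed: int = 0,
) -> np.ndarray:
    """Simulate shutter-closed dark frames (offset + read noise only)."""
    n = camera.n_dark_frames if n_frames is None else n_frames
    rng = np.random.default_rng(seed)
    zeros = np.zeros((n, *shape))
    read = rng.normal(0.0, camera.read_noise_e, size=zeros.shape)
    counts = read / camera.e_per_count + camera.offset_counts
    return np.clip(np.rint(counts), 0, 65535).astype(np.uint16)


def dark_calibrate(dark: np.ndarray) -> np.ndarray:
    """Pixelwise mean offset map from a dark-frame stack (>= 2 frames)."""
    dark = np.asarray(dark)
    if dark.ndim != 3 or len(dark) < 2:
        raise ValueError("need a stack of >= 2 dark frames")
    return dark.mean(axis=0)


def counts_to_photons(
    frame: np.ndarray, camera: CameraModel, offset_map: np.ndarray | None = None
) -> np.ndarray:
    """Convert raw counts to photon units: (counts - offset) * conv / gain.

    Subtracts the dark-calibration offset map (clamped at zero) first when
    given; pass ``offset_map=None`` for frames already dark-subtracted.
    """
    f = frame.astype(float)
    if offset_map is not None:
        f = np.clip(f - offset_map, 0.0, None)
    return f * camera.e_per_count / (camera.em_gain * camera.quantum_efficiency)
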