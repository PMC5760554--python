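"""Tilted Gaussian light-sheet and epi-illumination intensity models.

The sheet propagates along an axis tilted downward by ``tilt_deg`` about
the width (y) axis; at the waist it has a 1/e^2 thickness radius ``waist_um``
in the sheet-normal direction and a fixed 1/e^2 half-width ``width_um`` in y.
Thickness follows the Gaussian-beam hyperbolic law parameterized directly
by the configured confocal parameter (twice the Rayleigh range); waist and
confocal parameter are treated as independent measured properties of the
sheet rather than being derived from one another, which accommodates a
mildly aberrated real sheet.  Epi-illumination is modeled as z-uniform
over the simulated cell extent.

Coordinates are object-space µm: x along the field (sheet propagation
projects onto +x), y across the width, z height above the coverslip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SheetParams",
    "IlluminationField",
    "SlabPhantom",
    "intensity_at",
    "scan_positions",
    "background_rate",
    "sbr",
]


@dataclass(frozen=True)
class SheetParams:
    """Tilted Gaussian sheet geometry (all lengths µm, angle degrees)."""

    waist_um: float = 2.1
    width_um: float = 19.0
    confocal_um: float = 73.0
    tilt_deg: float = 10.0
    wavelength_nm: float = 647.0
    center_height_um: float = 0.0  # sheet-center height at field center (x=0)
    waist_offset_um: float = 0.0  # waist position along propagation from x=0

    def __post_init__(self) -> None:
        if self.waist_um <= 0:
            raise ValueError("waist must be positive")
        if not 0.0 <= self.tilt_deg < 45.0:
            raise ValueError("tilt must be in [0, 45) degrees")
        if self.width_um < self.waist_um:
            raise ValueError("width must be >= waist")


@dataclass(frozen=True)
class IlluminationField:
    """Either a z-uniform epi field or a tilted Gaussian sheet."""

    mode: str = "sheet"
    peak_intensity: float = 1.0
    sheet: SheetParams | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("epi", "sheet"):
            raise ValueError("mode must be 'epi' or 'sheet'")
        if self.mode == "sheet" and self.sheet is None:
            object.__setattr__(self, "sheet", SheetParams())

    def with_offset(self, dz_um: float) -> "IlluminationField":
        """Copy of this field with the sheet raised by ``dz_um`` (slice scan)."""
        if self.mode == "epi":
            return self
        s = self.sheet
        return IlluminationField(
            mode="sheet",
            peak_intensity=self.peak_intensity,
            sheet=SheetParams(
                waist_um=s.waist_um,
                width_um=s.width_um,
                confocal_um=s.confocal_um,
                tilt_deg=s.tilt_deg,
                wavelength_nm=s.wavelength_nm,
                center_height_um=s.center_height_um + dz_um,
                waist_offset_um=s.waist_offset_um,
            ),
        )


def intensity_at(field: IlluminationField, point_um) -> np.ndarray:
    """Relative illumination intensity at object-space point(s) (x, y, z) µm.

    Normalized so the sheet-waist center (epi: everywhere) is 1.0.  The
    amplitude factor w0/w(s) along propagation conserves the power
    integrated across the sheet normal.
    """
    p = np.asarray(point_um, dtype=float)
    x, y, z = p[..., 0], p[..., 1], p[..., 2]
    if field.mode == "epi":
        return field.peak_intensity * np.ones_like(x)
    s = field.sheet
    th = np.deg2rad(s.tilt_deg)
    # sheet frame: propagation coordinate xi, normal coordinate nu
    dz = z - s.center_height_um
    xi = x * np.cos(th) - dz * np.sin(th) - s.waist_offset_um
    nu = x * np.sin(th) + dz * np.cos(th)
    zr = s.confocal_um / 2.0
    w = s.waist_um * np.sqrt(1.0 + (xi / zr) ** 2)
    i_norm = (s.waist_um / w) * np.exp(-2.0 * (nu / w) ** 2)
    i_width = np.exp(-2.0 * (y / s.width_um) ** 2)
    return field.peak_intensity * i_norm * i_width


def sheet_center_height(field: IlluminationField, x_um: float) -> float:
    """Height of the sheet center above the coverslip at field position x."""
    if field.mode == "epi":
        raise ValueError("epi field has no sheet center")
    s = field.sheet
    return s.center_height_um - x_um * np.tan(np.deg2rad(s.tilt_deg))


def scan_positions(start_um: float, stop_um: float, step_um: float) -> list[tuple[int, float]]:
    """Inclusive arithmetic ladder of axial sheet offsets, one per slice.

    Returns ``[(slice_index, offset_um), ...]``.  Mirrors the stepwise
    axial scan in which the focal plane moves together with the sheet.
    """
    if step_um <= 0:
        raise ValueError("step must be positive")
    if stop_um < start_um:
        raise ValueError("empty scan range")
    n = int(np.floor((stop_um - start_um) / step_um + 1e-9)) + 1
    return [(i, start_um + i * step_um) for i in range(n)]


@dataclass(frozen=True)
class SlabPhantom:
    """Laterally uniform fluorophore slab: density (µm^-3) between two heights."""

    z_min_um: float
    z_max_um: float
    density_per_um3: float = 1.0

    def density(self, z_um: np.ndarray) -> np.ndarray:
        inside = (z_um >= self.z_min_um) & (z_um <= self.z_max_um)
        return np.where(inside, self.density_per_um3, 0.0)


def background_rate(
    field: IlluminationField,
    phantom: SlabPhantom,
    focal_z_um: float,
    photons_per_emitter: float = 1.0,
    pixel_nm: float = 160.0,
    quad_step_um: float = 0.02,
) -> float:
    """Mean out-of-focus background, photons per camera pixel per frame.

    Integrates emitter density x illumination intensity over the labeled
    volume by deterministic quadrature.  For a laterally uniform slab the
    defocused-PSF lateral spread redistributes but conserves energy within
    a pixel column, so each z-layer contributes its full areal emission
    rate; the layer at the focal plane is treated identically, making the
    measure a conservative (upper) background estimate.
    """
    if phantom.density_per_um3 < 0:
        raise ValueError("density must be >= 0")
    if phantom.density_per_um3 == 0:
        return 0.0
    z = np.arange(phantom.z_min_um, phantom.z_max_um + quad_step_um / 2, quad_step_um)
    pts = np.stack([np.zeros_like(z), np.zeros_like(z), z], axis=-1)
    inten = intensity_at(field, pts)
    areal = np.trapezoid(phantom.density(z) * inten, z)  # emitters/µm² weighted
    px_area_um2 = (pixel_nm * 1e-3) ** 2
    return float(areal * px_area_um2 * photons_per_emitter)


def sbr(signal_photons: float, background_per_px: float, psf_peak_fraction: float) -> float:
    """Signal-to-background ratio: peak-pixel signal over per-pixel background.

    ``psf_peak_fraction`` is the fraction of the emitter's photons landing
    in the brightest pixel (max of the normalized pixelated PSF), so the
    comparison is computed identically for any illumination mode.  Zero
    background with nonzero signal reports ``inf``.
    """
    if background_per_px < 0:
        raise ValueError("background must be >= 0")
    peak = signal_photons * psf_peak_fraction
    if background_per_px == 0:
        return float("inf") if peak > 0 else 0.0
    return float(peak / background_per_px)
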