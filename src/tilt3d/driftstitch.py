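"""Drift correction and axial slice stitching.

Three concerns live here:

* **Live axial feedback** — during acquisition the fiducial z estimate is
  compared against a setpoint and the difference fed back to the focal
  plane with one interleave period of latency, bounding residual axial
  drift by (period x drift rate) in the linear-drift case.
* **Post-hoc drift correction** — fiducial tracks sampled every Nth frame
  are interpolated linearly to all frames and subtracted from the
  localization table.
* **Slice stitching** — localization tables acquired at stepped focal/sheet
  offsets overlap axially (the 2 µm double-helix range exceeds the 1 µm
  step); the residual inter-slice offset is recovered by cross-correlating
  z histograms of the shared region and chained from the bottom slice.

All positions are nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DriftTrace",
    "live_axial_feedback",
    "simulate_feedback_loop",
    "trace_from_track",
    "apply_drift_correction",
    "stitch_slices",
]


@dataclass
class DriftTrace:
    """Per-frame (dx, dy, dz) drift estimate covering every SM frame."""

    frames: np.ndarray  # (n,) frame indices, ascending
    drift_nm: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.drift_nm = np.asarray(self.drift_nm, dtype=float)
        if not np.all(np.diff(self.frames) > 0):
            raise ValueError("trace frames must be strictly increasing")
        if len(self.frames) != len(self.drift_nm):
            raise ValueError("frames and drift disagree")

    def at(self, frames: np.ndarray) -> np.ndarray:
        """Linear interpolation of the trace onto arbitrary frames."""
        f = np.asarray(frames, dtype=float)
        return np.stack(
            [np.interp(f, self.frames, self.drift_nm[:, k]) for k in range(3)],
            axis=-1,
        )


def live_axial_feedback(measured_z_nm: float, setpoint_nm: float) -> float:
    """Focal-plane correction (nm) from one fiducial measurement.

    The correction re-centers the measured fiducial height on the
    setpoint; it applies to frames *after* the fiducial frame (one
    interleave period of latency).
    """
    return setpoint_nm - measured_z_nm


def simulate_feedback_loop(
    drift_z_nm: np.ndarray,
    period: int,
    measurement_noise_nm: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Closed-loop residual axial error per frame for a given drift trace.

    Every ``period``-th frame (1-based) the apparent fiducial height
    (drift minus applied correction, plus measurement noise) is measured
    and the correction updated for subsequent frames.  Returns the
    residual (drift + correction) per frame; for linear drift at rate v
    the residual is a sawtooth bounded by ``period * v``.
    """
    if period < 1:
        raise ValueError("period must be >= 1")
    rng = rng or np.random.default_rng(0)
    n = len(drift_z_nm)
    corr = 0.0
    residual = np.empty(n)
    for f in range(n):
        residual[f] = drift_z_nm[f] + corr
        if (f + 1) % period == 0:
            measured = residual[f]
            if measurement_noise_nm > 0:
                measured += rng.normal(0.0, measurement_noise_nm)
            corr += live_axial_feedback(measured, 0.0)
    return residual


def trace_from_track(track_table: pd.DataFrame, reference: str = "start") -> DriftTrace:
    """Build a drift trace from a fiducial track table.

    The track's (x, y, z) relative to a reference is the measured sample
    drift.  ``reference='start'`` (default) extrapolates a linear fit of
    the track back to frame 0, so drift accumulated before the first
    fiducial frame does not offset the whole reconstruction; ``'first'``
    uses the first sample, ``'mean'`` the track mean.  Multiple fiducials
    can be combined by averaging their traces before this step.
    """
    t = track_table.dropna(subset=["x_nm", "y_nm", "z_nm"])
    xyz = t[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    frames = t["frame"].to_numpy(dtype=float)
    if reference == "start" and len(t) > 2:
        # fit only the early track: over long spans slow non-linear drift
        # (random-walk component) corrupts the frame-0 intercept
        # short window: measurement noise averages out after a few samples,
        # while the random-walk drift component grows with window length
        k_fit = min(8, len(t))
        ref = np.array([
            np.polynomial.Polynomial.fit(frames[:k_fit], xyz[:k_fit, k], 1)(0.0)
            for k in range(3)
        ])
    elif reference == "mean":
        ref = xyz.mean(axis=0)
    else:
        ref = xyz[0]
    return DriftTrace(frames=t["frame"].to_numpy(), drift_nm=xyz - ref)


def apply_drift_correction(locs: pd.DataFrame, trace: DriftTrace) -> pd.DataFrame:
    """Subtract the interpolated drift from a localization table.

    Returns a corrected copy; the caller should not re-apply the same
    trace.  Frames outside the trace span use its end values (the trace
    covers every SM frame in a well-formed acquisition).
    """
    out = locs.copy()
    d = trace.at(out["frame"].to_numpy())
    out["x_nm"] = out["x_nm"] - d[:, 0]
    out["y_nm"] = out["y_nm"] - d[:, 1]
    zcol = "z_abs_nm" if "z_abs_nm" in out.columns else "z_nm"
    out[zcol] = out[zcol] - d[:, 2]
    return out


def _hist_xcorr_offset(
    za: np.ndarray, zb: np.ndarray, bin_nm: float, max_shift_nm: float
) -> float:
    """Sub-bin offset that best aligns two z samples via histogram xcorr.

    Positive result means ``zb`` sits higher than ``za`` by that amount.
    """
    lo = min(za.min(), zb.min()) - max_shift_nm
    hi = max(za.max(), zb.max()) + max_shift_nm
    edges = np.arange(lo, hi + bin_nm, bin_nm)
    ha, _ = np.histogram(za, bins=edges)
    hb, _ = np.histogram(zb, bins=edges)
    ha = ha - ha.mean()
    hb = hb - hb.mean()
    cc = np.correlate(hb, ha, mode="full")
    lags = np.arange(-len(ha) + 1, len(ha))
    keep = np.abs(lags) * bin_nm <= max_shift_nm
    cc, lags = cc[keep], lags[keep]
    k = int(np.argmax(cc))
    shift = float(lags[k])
    if 0 < k < len(cc) - 1:
        denom = cc[k - 1] - 2.0 * cc[k] + cc[k + 1]
        if denom != 0:
            shift += float(np.clip(0.5 * (cc[k - 1] - cc[k + 1]) / denom, -1, 1))
    return shift * bin_nm


def stitch_slices(
    slice_tables: list[pd.DataFrame],
    nominal_focals_nm: list[float] | None = None,
    coverage_half_nm: float = 800.0,
    bin_nm: float = 10.0,
    max_residual_nm: float = 300.0,
    fiducial_offsets_nm: list[float] | None = None,
    z_col: str = "z_abs_nm",
    refine: bool = True,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Merge per-slice localization tables into one axially consistent table.

    Adjacent slices image overlapping z ranges of the same structure; any
    residual offset between them (beyond the nominal focal step, already
    contained in ``z_abs_nm``) is estimated by cross-correlating the z
    histograms of the overlap region with sub-bin parabolic refinement,
    optionally initialized by shared-fiducial offsets, and chained upward
    from the bottom slice.

    When ``nominal_focals_nm`` is given, the overlap region for each
    adjacent pair is the intersection of both slices' well-localized
    bands (focal +- ``coverage_half_nm``), so coverage fall-off near the
    working-range edges does not skew the correlation; otherwise the
    common span of the data is used.

    With ``refine=False`` the histogram refinement is skipped and only the
    shared-fiducial offsets are applied — the right choice when the overlap
    region has little blind z structure (e.g. the flat z profile of a
    spherical shell) and a fiducial tracked through all slices already
    pins the inter-slice registration.

    Returns the merged table (with ``slice`` provenance column preserved
    and corrected z) and the per-slice applied corrections (nm).
    """
    if len(slice_tables) < 2:
        raise ValueError("need >= 2 slices to stitch")
    n = len(slice_tables)
    residuals = np.zeros(n)
    for i in range(1, n if refine else 1):
        a = slice_tables[i - 1][z_col].to_numpy(dtype=float)
        b = slice_tables[i][z_col].to_numpy(dtype=float) - (
            fiducial_offsets_nm[i] - fiducial_offsets_nm[i - 1]
            if fiducial_offsets_nm is not None
            else 0.0
        )
        a = a[np.isfinite(a)]
        b = b[np.isfinite(b)]
        if nominal_focals_nm is not None:
            lo = max(nominal_focals_nm[i - 1], nominal_focals_nm[i]) - coverage_half_nm
            hi = min(nominal_focals_nm[i - 1], nominal_focals_nm[i]) + coverage_half_nm
        else:
            lo = max(a.min(), b.min()) - max_residual_nm
            hi = min(a.max(), b.max()) + max_residual_nm
        a_ov = a[(a >= lo) & (a <= hi)]
        b_ov = b[(b >= lo) & (b <= hi)]
        if len(a_ov) == 0 or len(b_ov) == 0:
            residuals[i] = 0.0  # no overlap: fall back to fiducial offsets only
            continue
        residuals[i] = _hist_xcorr_offset(a_ov, b_ov, bin_nm, max_residual_nm)

    corrections = np.cumsum(residuals)
    if fiducial_offsets_nm is not None:
        corrections = corrections + (
            np.asarray(fiducial_offsets_nm) - fiducial_offsets_nm[0]
        )
    merged = []
    for i, tab in enumerate(slice_tables):
        t = tab.copy()
        t[z_col] = t[z_col] - corrections[i]
        if "slice" not in t.columns:
            t["slice"] = i
        merged.append(t)
    return pd.concat(merged, ignore_index=True), corrections
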