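"""Closed-loop axial feedback, drift correction, slice stitching."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tilt3d import driftstitch as ds


@settings(deadline=None, derandomize=True, max_examples=25)
@given(seed=st.integers(0, 10_000))
def test_drift_correction_never_worsens_true_trace(seed):
    """Correcting with the true trace recovers the undrifted table exactly."""
    rng = np.random.default_rng(seed)
    frames = np.arange(0, 200, 20)
    walk = np.cumsum(rng.normal(0, 5, (10, 3)), axis=0)
    trace = ds.DriftTrace(frames, walk)
    locs = pd.DataFrame({
        "frame": rng.integers(0, 180, 50),
        "x_nm": rng.normal(0, 100, 50),
        "y_nm": rng.normal(0, 100, 50),
        "z_abs_nm": rng.normal(0, 100, 50),
    })
    d = trace.at(locs.frame.to_numpy())
    drifted = locs.copy()
    drifted[["x_nm", "y_nm", "z_abs_nm"]] += d
    out = ds.apply_drift_correction(drifted, trace)
    assert np.abs(
        out[["x_nm", "y_nm", "z_abs_nm"]].to_numpy()
        - locs[["x_nm", "y_nm", "z_abs_nm"]].to_numpy()
    ).max() < 1e-9


class TestFeedback:
    def test_zero_correction_at_setpoint(self):
        assert ds.live_axial_feedback(120.0, 120.0) == 0.0

    def test_correction_recentres_measurement(self):
        assert ds.live_axial_feedback(130.0, 100.0) == -30.0

    def test_linear_drift_sawtooth_bound(self):
        rate, period = 0.5, 20
        drift = rate * np.arange(400)
        resid = ds.simulate_feedback_loop(drift, period)
        assert np.abs(resid[period:]).max() <= period * rate + 1e-9

    def test_without_feedback_drift_unbounded(self):
        drift = 0.5 * np.arange(400)
        resid = ds.simulate_feedback_loop(drift, 20)
        assert np.abs(drift).max() > 10 * np.abs(resid[20:]).max()

    def test_period_validation(self):
        with pytest.raises(ValueError):
            ds.simulate_feedback_loop(np.zeros(10), 0)


class TestDriftCorrection:
    def make_locs(self, n=200):
        return pd.DataFrame({
            "frame": np.arange(n), "x_nm": 0.0, "y_nm": 0.0, "z_abs_nm": 0.0,
        })

    def test_zero_trace_identity(self):
        locs = self.make_locs()
        trace = ds.DriftTrace(np.arange(0, 200, 20), np.zeros((10, 3)))
        out = ds.apply_drift_correction(locs, trace)
        pd.testing.assert_frame_equal(out, locs)

    def test_true_random_walk_trace_fully_corrects(self):
        rng = np.random.default_rng(0)
        frames = np.arange(0, 200, 20)
        walk = np.cumsum(rng.normal(0, 3, (10, 3)), axis=0)
        trace = ds.DriftTrace(frames, walk)
        locs = self.make_locs()
        d = trace.at(locs.frame.to_numpy())
        drifted = locs.copy()
        drifted["x_nm"] += d[:, 0]
        drifted["y_nm"] += d[:, 1]
        drifted["z_abs_nm"] += d[:, 2]
        out = ds.apply_drift_correction(drifted, trace)
        assert np.abs(out[["x_nm", "y_nm", "z_abs_nm"]].to_numpy()).max() < 1e-9

    def test_linear_drift_interpolation_exact(self):
        # samples every 20 frames of a linear drift: interp error is zero
        frames = np.arange(0, 201, 20)
        trace = ds.DriftTrace(frames, np.outer(frames, [0.5, -0.2, 0.1]))
        locs = self.make_locs(201)
        drifted = locs.copy()
        drifted["x_nm"] += 0.5 * drifted["frame"]
        out = ds.apply_drift_correction(drifted, trace)
        assert np.abs(out["x_nm"].to_numpy()).max() < 1e-9

    def test_trace_frames_must_increase(self):
        with pytest.raises(ValueError):
            ds.DriftTrace(np.array([0, 0, 20]), np.zeros((3, 3)))

    def test_trace_from_track_start_reference(self):
        # linear bead motion extrapolates to zero drift at frame 0
        frames = np.arange(19, 419, 20)
        table = pd.DataFrame({
            "frame": frames,
            "x_nm": 100.0 + 0.5 * frames,
            "y_nm": -50.0, "z_nm": 900.0 + 0.2 * frames,
        })
        trace = ds.trace_from_track(table)
        assert trace.drift_nm[0, 0] == pytest.approx(0.5 * 19, abs=1e-6)
        assert trace.drift_nm[0, 2] == pytest.approx(0.2 * 19, abs=1e-6)


class TestStitching:
    def cloud(self, n=4000, seed=0):
        rng = np.random.default_rng(seed)
        return rng.normal(2500.0, 400.0, n)

    def table(self, z):
        return pd.DataFrame({"frame": np.arange(len(z)), "x_nm": 0.0,
                             "y_nm": 0.0, "z_abs_nm": z})

    def test_identical_slices_zero_offset(self):
        z = self.cloud()
        _, corr = ds.stitch_slices([self.table(z), self.table(z.copy())])
        assert abs(corr[1]) <= 5.0  # half a bin

    def test_injected_37nm_recovered(self):
        z = self.cloud()
        merged, corr = ds.stitch_slices([self.table(z), self.table(z + 37.0)])
        assert corr[1] == pytest.approx(37.0, abs=5.0)
        assert merged[merged["slice"] == 1].z_abs_nm.mean() == pytest.approx(
            z.mean(), abs=6.0
        )

    @pytest.mark.parametrize("offset", [-250.0, -80.0, 120.0, 280.0])
    def test_offsets_within_search_range_recovered(self, offset):
        z = self.cloud(seed=3)
        _, corr = ds.stitch_slices([self.table(z), self.table(z + offset)])
        assert corr[1] == pytest.approx(offset, abs=5.0)

    def test_three_slice_chain_additive(self):
        z = self.cloud(seed=5)
        a, b = 37.0, -60.0
        _, corr = ds.stitch_slices(
            [self.table(z), self.table(z + a), self.table(z + a + b)]
        )
        assert corr[2] == pytest.approx(a + b, abs=7.0)

    def test_no_overlap_falls_back_to_fiducial_offsets(self):
        za = self.cloud(seed=1)
        zb = za + 5000.0  # disjoint
        _, corr = ds.stitch_slices(
            [self.table(za), self.table(zb)],
            nominal_focals_nm=[2500.0, 3500.0], coverage_half_nm=400.0,
            fiducial_offsets_nm=[0.0, 12.0],
        )
        assert corr[1] == pytest.approx(12.0)

    def test_refine_off_applies_fiducial_only(self):
        z = self.cloud(seed=2)
        _, corr = ds.stitch_slices(
            [self.table(z), self.table(z + 37.0)],
            fiducial_offsets_nm=[0.0, 20.0], refine=False,
        )
        assert corr[1] == pytest.approx(20.0)

    def test_requires_two_slices(self):
        with pytest.raises(ValueError):
            ds.stitch_slices([self.table(self.cloud())])
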