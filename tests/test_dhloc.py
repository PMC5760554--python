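"""Double-helix localization: detection, fitting, calibration, filtering."""

import numpy as np
import pandas as pd
import pytest

from tilt3d import dhloc, optics


PX = 160.0


def synthetic_roi(x1, y1, x2, y2, a1, a2, sigma, bg, n=25):
    c = (np.arange(n) - n // 2) * PX
    x, y = np.meshgrid(c, c)
    return dhloc._double_gauss(np.array([x1, y1, x2, y2, a1, a2, sigma, bg]), x, y)


class TestDetection:
    def test_blank_frame_empty(self):
        rng = np.random.default_rng(0)
        frame = rng.normal(5.0, 0.3, (64, 64))
        assert dhloc.detect_candidates(frame, 850.0, PX) == []

    def test_single_emitter_found_within_pixel(self, config, dh_mask):
        frame = np.full((64, 64), 5.0)
        frame += 3000.0 * optics.psf_at(dh_mask, 0.3, config, PX, 64,
                                        shift_nm=(480.0, -320.0), max_clip=None)
        peaks = dhloc.detect_candidates(frame, 850.0, PX)
        assert len(peaks) == 1
        iy, ix = peaks[0]
        assert abs(ix - (32 + 3)) <= 1 and abs(iy - (32 - 2)) <= 1

    def test_two_separated_emitters(self, config, dh_mask):
        frame = np.full((94, 94), 5.0)
        roi = 3000.0 * optics.psf_at(dh_mask, 0.0, config, PX, 32, max_clip=None)
        for sx, sy in ((-3000.0, -3000.0), (3000.0, 3000.0)):
            cy, cx = 47 + int(sy / PX), 47 + int(sx / PX)
            frame[cy - 16 : cy + 16, cx - 16 : cx + 16] += roi
        assert len(dhloc.detect_candidates(frame, 850.0, PX)) == 2


class TestDoubleGaussianFit:
    def test_noiseless_roundtrip_hundredth_pixel(self):
        truth = (-420.0, 130.0, 410.0, -150.0, 80.0, 75.0, 170.0, 3.0)
        roi = synthetic_roi(*truth)
        fit = dhloc.fit_double_gaussian(roi, PX)
        assert fit.converged
        got = {(fit.x1, fit.y1), (fit.x2, fit.y2)}
        for cx, cy in ((truth[0], truth[1]), (truth[2], truth[3])):
            assert min(np.hypot(gx - cx, gy - cy) for gx, gy in got) < 0.01 * PX

    def test_single_gaussian_rejected_as_collapse(self):
        roi = synthetic_roi(0.0, 0.0, 0.0, 0.0, 60.0, 60.0, 170.0, 2.0)
        fit = dhloc.fit_double_gaussian(roi, PX)
        assert not fit.converged

    def test_mirror_symmetry(self):
        roi = synthetic_roi(-400.0, 120.0, 400.0, -120.0, 70.0, 70.0, 170.0, 1.0)
        fit = dhloc.fit_double_gaussian(roi, PX)
        fit_m = dhloc.fit_double_gaussian(roi[::-1, :].copy(), PX)
        # mirroring about the x axis negates the y coordinates
        ys = sorted([fit.y1, fit.y2])
        ys_m = sorted([-fit_m.y1, -fit_m.y2])
        assert np.allclose(ys, ys_m, atol=0.5)
        assert fit.residual == pytest.approx(fit_m.residual, rel=1e-3, abs=1e-6)

    def test_whole_pixel_translation_equivariance(self, config, dh_mask):
        a = 3000.0 * optics.psf_at(dh_mask, 0.4, config, PX, 25,
                                   shift_nm=(40.0, -30.0), max_clip=None)
        fit_a = dhloc.fit_double_gaussian(a, PX)
        big = np.zeros((31, 31))
        big[5:30, 2:27] = a  # shift by (+2 col, -10... rows) -> use offsets
        # simpler: shift content by exactly 2 pixels right, 3 down in a frame
        b = np.zeros_like(a)
        b[3:, 2:] = a[:-3, :-2]
        fit_b = dhloc.fit_double_gaussian(b, PX)
        mx_a, my_a = fit_a.midpoint
        mx_b, my_b = fit_b.midpoint
        assert mx_b - mx_a == pytest.approx(2 * PX, abs=3.0)
        assert my_b - my_a == pytest.approx(3 * PX, abs=3.0)


class TestCalibration:
    def test_valid_range_spans_working_depth(self, dh_calibration):
        lo, hi = dh_calibration.z_valid_nm
        assert hi - lo >= 1800.0

    def test_decimated_stack_agrees(self, config, dh_mask, dh_calibration):
        z = np.arange(-1.1, 1.1001, 0.1)  # 2x coarser
        stack = optics.render_stack(dh_mask, z, config,
                                    dx_nm=config.effective_pixel_nm,
                                    n_pixels=32, max_clip=None)
        cal2 = dhloc.calibrate_dh(stack)
        for ang in (-60.0, -20.0, 0.0, 20.0, 60.0):
            z1 = dh_calibration.z_from_angle(dh_calibration.ref_angle_deg + ang)
            z2 = cal2.z_from_angle(cal2.ref_angle_deg + ang)
            assert z1 == pytest.approx(z2, abs=5.0)

    def test_reversed_stack_identical(self, config, dh_mask, dh_calibration):
        z = np.arange(-1.1, 1.1001, 0.05)[::-1]
        stack = optics.render_stack(dh_mask, z, config,
                                    dx_nm=config.effective_pixel_nm,
                                    n_pixels=32, max_clip=None)
        cal_r = dhloc.calibrate_dh(stack)
        assert np.allclose(cal_r.z_nm, dh_calibration.z_nm)
        assert np.allclose(cal_r.angle_deg, dh_calibration.angle_deg, atol=1e-9)

    def test_short_stack_rejected(self, config, dh_mask):
        z = np.arange(-0.2, 0.2001, 0.05)
        stack = optics.render_stack(dh_mask, z, config,
                                    dx_nm=config.effective_pixel_nm,
                                    n_pixels=32, max_clip=None)
        with pytest.raises(ValueError, match="monotone"):
            dhloc.calibrate_dh(stack)


class TestInversion:
    def test_reference_angle_maps_to_focus(self, dh_calibration):
        z = dh_calibration.z_from_angle(dh_calibration.ref_angle_deg)
        assert z == pytest.approx(0.0, abs=2.0)

    def test_noiseless_render_recovers_z(self, config, dh_mask, dh_calibration):
        roi = 3000.0 * optics.psf_at(dh_mask, 0.5, config, PX, 25, max_clip=None)
        fit = dhloc.fit_double_gaussian(roi, PX)
        rec = dhloc.lobe_pair_to_xyz(fit, dh_calibration)
        assert rec["z_nm"] == pytest.approx(500.0, abs=10.0)

    def test_lobe_label_swap_invariance(self, dh_calibration):
        a = dhloc.FitResult(-400.0, 100.0, 400.0, -100.0, 50.0, 60.0, 170.0,
                            1.0, 0.01, True)
        b = dhloc.FitResult(400.0, -100.0, -400.0, 100.0, 60.0, 50.0, 170.0,
                            1.0, 0.01, True)
        ra = dhloc.lobe_pair_to_xyz(a, dh_calibration)
        rb = dhloc.lobe_pair_to_xyz(b, dh_calibration)
        for k in ("x_nm", "y_nm", "z_nm", "photons"):
            assert ra[k] == pytest.approx(rb[k], abs=1e-9, nan_ok=True)

    def test_out_of_range_angle_tagged(self, dh_calibration):
        lo, hi = (dh_calibration._agrid[0], dh_calibration._agrid[-1])
        beyond = max(lo, hi) + 5.0 + dh_calibration.ref_angle_deg
        th = np.deg2rad(beyond)
        fit = dhloc.FitResult(
            400 * np.cos(th), 400 * np.sin(th), -400 * np.cos(th),
            -400 * np.sin(th), 50.0, 50.0, 170.0, 1.0, 0.01, True,
        )
        rec = dhloc.lobe_pair_to_xyz(fit, dh_calibration)
        assert rec["reason"] == "z_out_of_range"
        assert np.isnan(rec["z_nm"])


class TestFiltering:
    def make_locs(self):
        return pd.DataFrame({
            "frame": [0, 1, 2, 3],
            "x_nm": 0.0, "y_nm": 0.0,
            "z_nm": [100.0, 200.0, np.nan, -950.0],
            "photons": [1500.0, 90.0, 1500.0, 1500.0],
            "background": 2.0,
            "angle_deg": 0.0,
            "separation_nm": [850.0, 850.0, 850.0, 850.0],
            "asymmetry": [1.2, 1.1, 1.0, 10.0],
            "residual": [0.05, 0.05, 0.05, 0.05],
            "slice": 0, "reason": "",
        })

    def test_empty_policy_identity(self):
        locs = self.make_locs()
        out = dhloc.filter_localizations(
            locs, dhloc.FilterPolicy(max_residual=None, max_asymmetry=None,
                                     max_separation_dev=None, min_photons=None,
                                     require_z=False)
        )
        assert len(out) == len(locs)

    def test_default_policy_drops_bad_records(self):
        out = dhloc.filter_localizations(self.make_locs(), dhloc.FilterPolicy())
        assert len(out) == 1
        assert out.iloc[0].frame == 0

    def test_survivors_monotone_in_threshold(self):
        locs = self.make_locs()
        counts = [
            len(dhloc.filter_localizations(
                locs, dhloc.FilterPolicy(min_photons=p, max_asymmetry=None,
                                         max_residual=None, require_z=False)))
            for p in (0.0, 100.0, 1000.0, 2000.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_z_range_trim(self):
        out = dhloc.filter_localizations(
            self.make_locs(),
            dhloc.FilterPolicy(max_abs_z_nm=900.0, max_asymmetry=None,
                               min_photons=None, max_residual=None),
        )
        assert -950.0 not in out["z_nm"].to_numpy()


class TestEmpiricalPrecision:
    def test_identical_repeats_zero_scatter(self):
        locs = pd.DataFrame({
            "frame": np.arange(25), "x_nm": 5.0, "y_nm": -3.0, "z_nm": 100.0,
        })
        p = dhloc.empirical_precision(locs)
        for v in p.values():
            assert v == pytest.approx(0.0, abs=1e-9)

    def test_linear_drift_removed(self):
        f = np.arange(40, dtype=float)
        locs = pd.DataFrame({
            "frame": f, "x_nm": 2.0 * f, "y_nm": 0.0, "z_nm": -1.5 * f,
        })
        p = dhloc.empirical_precision(locs)
        assert p["x_nm"] == pytest.approx(0.0, abs=1e-9)
        assert p["z_nm"] == pytest.approx(0.0, abs=1e-9)

    def test_requires_twenty_repeats(self):
        locs = pd.DataFrame({"frame": range(5), "x_nm": 0.0, "y_nm": 0.0,
                             "z_nm": 0.0})
        with pytest.raises(ValueError):
            dhloc.empirical_precision(locs)
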