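"""Synthetic microscope: phantoms, schedule, noise chain, calibration."""

import numpy as np
import pytest

from tilt3d import optics, scope


class TestPhantoms:
    def test_shell_count_matches_area_density(self):
        ph = scope.make_phantom("lamina_shell", 20.0, seed=1, radius_um=2.0)
        lam = 4.0 * np.pi * 4.0 * 20.0
        assert abs(ph.n_emitters - lam) < 4.0 * np.sqrt(lam)

    def test_shell_emitters_near_surface(self):
        ph = scope.make_phantom(
            "lamina_shell", 20.0, seed=1, center_um=(0, 0, 3.0),
            radius_um=2.0, thickness_nm=100.0,
        )
        r = np.linalg.norm(
            np.column_stack([ph.positions[:, 0] * 1e-3, ph.positions[:, 1] * 1e-3,
                             ph.positions[:, 2] - 3.0]), axis=1,
        )
        assert np.all(np.abs(r - 2.0) <= 0.1 + 1e-9)  # truncated at +-thickness

    def test_cylinder_radial_distances_bounded(self):
        ph = scope.make_phantom(
            "mito_cylinder", 100.0, seed=2, center_um=(0, 0, 1.0),
            radius_um=0.15, thickness_nm=40.0, length_um=2.0,
        )
        r = np.hypot(ph.positions[:, 1], (ph.positions[:, 2] - 1.0) * 1e3)
        assert np.all(np.abs(r - 150.0) <= 20.0 + 1e-9)

    def test_same_seed_identical(self):
        a = scope.make_phantom("lamina_shell", 30.0, seed=7)
        b = scope.make_phantom("lamina_shell", 30.0, seed=7)
        assert np.array_equal(a.positions, b.positions)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            scope.make_phantom("lamina_shell", 30.0, seed=0, radius_um=0.0)
        with pytest.raises(ValueError):
            scope.make_phantom("points", 30.0, seed=0)


class TestSchedule:
    def test_fiducial_every_twentieth_frame(self):
        sched = scope.AcquisitionSchedule(slices=((0.0, 3.0),), frames_per_slice=60)
        roles = sched.roles()
        assert [i + 1 for i, r in enumerate(roles) if r == "fiducial"] == [20, 40, 60]
        assert roles[0] == "sm"

    def test_reactivation_takes_precedence_after_start(self):
        sched = scope.AcquisitionSchedule(
            fiducial_period=20, reactivation_period=100, reactivation_start=100,
            slices=((0.0, 3.0),), frames_per_slice=300,
        )
        roles = sched.roles()
        assert roles[199] == "reactivation"  # frame 200, both 20 | 200 and 100 | 200
        assert roles[99] == "fiducial"  # frame 100 not yet past the start
        assert roles[119] == "fiducial"

    def test_validation(self):
        with pytest.raises(ValueError):
            scope.AcquisitionSchedule(fiducial_period=0)
        with pytest.raises(ValueError):
            scope.AcquisitionSchedule(slices=())


@pytest.fixture(scope="module")
def tiny_stream(config, dh_mask, tp_mask):
    pts = scope.make_phantom(
        "points", positions=np.array([[0.0, 0.0, 3.2], [2000.0, 1000.0, 2.7]])
    )
    sched = scope.AcquisitionSchedule(slices=((0.0, 3.0),), frames_per_slice=25)
    return scope.simulate_stream(
        pts,
        scope.BlinkModel(initial_dark_fraction=0.0, on_to_off_rate=0.0,
                         bleach_rate=0.0),
        schedule=sched, masks={"sm": dh_mask, "fiducial": tp_mask}, seed=3,
        config=config,
    )


class TestStream:
    def test_same_seed_identical_stream(self, config, dh_mask, tp_mask, tiny_stream):
        pts = scope.make_phantom(
            "points", positions=np.array([[0.0, 0.0, 3.2], [2000.0, 1000.0, 2.7]])
        )
        sched = scope.AcquisitionSchedule(slices=((0.0, 3.0),), frames_per_slice=25)
        again = scope.simulate_stream(
            pts,
            scope.BlinkModel(initial_dark_fraction=0.0, on_to_off_rate=0.0,
                             bleach_rate=0.0),
            schedule=sched, masks={"sm": dh_mask, "fiducial": tp_mask}, seed=3,
            config=config,
        )
        assert np.array_equal(tiny_stream.frames, again.frames)

    def test_ground_truth_rerenders_bit_for_bit(self, tiny_stream):
        a = scope.expected_frame(tiny_stream, 0)
        b = scope.expected_frame(tiny_stream, 0)
        assert np.array_equal(a, b)
        # manual re-render from the log through the same emitter renderer
        rows = tiny_stream.truth[tiny_stream.truth.frame == 0]
        img = np.full_like(a, tiny_stream.background_photons["sm"])
        for r in rows.itertuples():
            scope._render_emitter(
                tiny_stream.masks["sm"], tiny_stream.config, img,
                r.x_nm, r.y_nm, r.z_um - tiny_stream.focal_z_um[0],
                r.photons, tiny_stream.pixel_nm,
            )
        assert np.array_equal(a, img)

    def test_photon_budget(self, tiny_stream):
        img = scope.expected_frame(tiny_stream, 0)
        signal = img.sum() - tiny_stream.background_photons["sm"] * img.size
        rows = tiny_stream.truth[tiny_stream.truth.frame == 0]
        expected = 0.0
        for r in rows.itertuples():
            roi = optics.psf_at(
                tiny_stream.masks["sm"], r.z_um - tiny_stream.focal_z_um[0],
                tiny_stream.config, tiny_stream.pixel_nm, 32, max_clip=None,
            )
            expected += r.photons * roi.sum()
        assert signal == pytest.approx(expected, rel=0.005)

    def test_frame_counts_track_expectation(self, tiny_stream):
        exp = scope.expected_frame(tiny_stream, 0)
        cam = tiny_stream.camera
        pred = exp.mean() * cam.em_gain / cam.e_per_count + cam.offset_counts
        assert tiny_stream.frames[0].mean() == pytest.approx(pred, rel=0.05)

    def test_empty_phantom_frames_are_offset_noise(self, config, dh_mask, tp_mask):
        pts = scope.make_phantom("points", positions=np.empty((0, 3)))
        sched = scope.AcquisitionSchedule(slices=((0.0, 3.0),), frames_per_slice=4)
        st = scope.simulate_stream(
            pts, schedule=sched, masks={"sm": dh_mask, "fiducial": tp_mask},
            seed=0, config=config, background_sm=0.0, fiducials_um=np.empty((0, 3)),
        )
        assert st.frames[0].mean() == pytest.approx(st.camera.offset_counts, abs=1.0)


class TestCameraCalibration:
    def test_constant_dark_frames(self):
        dark = np.full((5, 8, 8), 101, dtype=np.uint16)
        assert np.array_equal(scope.dark_calibrate(dark), np.full((8, 8), 101.0))

    def test_dark_map_standard_error(self):
        cam = scope.CameraModel()
        dark = scope.dark_frames(cam, 300, shape=(64, 64), seed=5)
        offmap = scope.dark_calibrate(dark)
        resid = offmap - cam.offset_counts
        assert np.mean(np.abs(resid) < 0.2) > 0.99
        assert abs(resid.mean()) < 0.05

    def test_requires_stack(self):
        with pytest.raises(ValueError):
            scope.dark_calibrate(np.zeros((1, 4, 4)))

    def test_counts_to_photons_inverts_gain(self):
        cam = scope.CameraModel(em_gain=186.0, e_per_count=1.0)
        counts = np.full((4, 4), 186.0 * 7.0)
        assert np.allclose(scope.counts_to_photons(counts, cam), 7.0)

    def test_unity_gain_identity(self):
        cam = scope.CameraModel(em_gain=1.0, e_per_count=1.0)
        counts = np.arange(16.0).reshape(4, 4)
        assert np.allclose(scope.counts_to_photons(counts, cam), counts)

    def test_poisson_source_mean_recovered(self):
        cam = scope.CameraModel()
        rng = np.random.default_rng(4)
        lam = np.full((200, 200), 1000.0)
        frame = scope._camera_noise(lam, cam, rng).astype(float)
        est = scope.counts_to_photons(
            frame, cam, offset_map=np.full(lam.shape, cam.offset_counts)
        )
        assert est.mean() == pytest.approx(1000.0, rel=0.02)
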