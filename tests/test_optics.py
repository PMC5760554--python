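"""Pupil engine: Fourier-plane sizing, mask construction, PSF physics, CRLB."""

import numpy as np
import pytest
from scipy import ndimage

from tilt3d import optics


class TestFourierPlaneDiameter:
    @pytest.mark.parametrize(
        "f_mm,expected",
        [(150.0, 4.2), (90.0, 2.5)],
    )
    def test_printed_field_diameters(self, f_mm, expected):
        cfg = optics.OpticalConfig(focal_length_4f_mm=f_mm)
        assert round(optics.fourier_plane_diameter(cfg), 1) == expected

    def test_zero_aperture_limit(self):
        cfg = optics.OpticalConfig(numerical_aperture=1e-9, focal_length_4f_mm=100.0)
        assert optics.fourier_plane_diameter(cfg) == pytest.approx(0.0, abs=1e-8)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            optics.OpticalConfig(magnification=1.0)  # M <= NA

    def test_na_beyond_immersion_rejected(self):
        with pytest.raises(ValueError):
            optics.OpticalConfig(numerical_aperture=1.6)


def test_effective_pixel_from_pitch_and_magnification():
    cfg = optics.OpticalConfig(camera_pixel_pitch_um=16.0, magnification=100.0)
    assert cfg.effective_pixel_nm == pytest.approx(160.0)


class TestMaskConstruction:
    def test_clear_mask_zero_phase(self, config):
        m = optics.build_mask("clear", config=config)
        assert np.abs(m.phase).max() == 0.0

    @pytest.mark.parametrize(
        "kind,rng", [("double_helix", 6.0), ("tetrapod", 2.0), ("nonsense", 2.0)]
    )
    def test_unsupported_combinations_rejected(self, config, kind, rng):
        with pytest.raises(ValueError):
            optics.build_mask(kind, rng, config=config)

    def test_dh_two_equal_lobes_at_focus(self, config, dh_mask):
        img = optics.psf_at(dh_mask, 0.0, config, 80.0, 96, max_clip=None)
        lab, n = ndimage.label(img > 0.3 * img.max())
        sums = np.sort(ndimage.sum_labels(img, lab, index=np.arange(1, n + 1)))
        assert n == 2
        assert sums[-1] / sums[-2] == pytest.approx(1.0, rel=0.05)

    def test_tetrapod_footprint_spreads_with_defocus(self, config, tp_mask):
        def second_moment(img, dx):
            c = np.arange(img.shape[0]) - img.shape[0] // 2
            x, y = np.meshgrid(c, c)
            s = img.sum()
            x0, y0 = (img * x).sum() / s, (img * y).sum() / s
            return np.sqrt(((img * ((x - x0) ** 2 + (y - y0) ** 2)).sum() / s)) * dx

        at = lambda z: second_moment(
            optics.psf_at(tp_mask, z, config, 160.0, 96, max_clip=None), 160.0
        )
        assert at(3.0) > at(0.0)
        assert at(-3.0) > at(0.0)

    def test_tetrapod_phase_is_smooth(self, config, tp_mask):
        # deformable-mirror realizable: bounded sample-to-sample gradient
        inside = tp_mask.grid.aperture() > 0
        for axis in (0, 1):
            d = np.abs(np.diff(tp_mask.phase, axis=axis))
            mask2 = inside[1:, :] & inside[:-1, :] if axis == 0 else inside[:, 1:] & inside[:, :-1]
            assert d[mask2].max() < np.pi / 2


class TestImageFormation:
    def test_airy_first_minimum(self, config):
        clear = optics.build_mask("clear", config=config)
        img = optics.psf_at(clear, 0.0, config, 10.0, 256, max_clip=None)
        c = 128
        prof = img[c, c:]
        mins = np.where((prof[1:-1] < prof[:-2]) & (prof[1:-1] < prof[2:]))[0]
        r_first = (mins[0] + 1) * 10.0
        airy = 0.61 * config.emission_wavelength_nm / config.numerical_aperture
        assert r_first == pytest.approx(airy, rel=0.05)

    def test_unit_sum_normalization(self, config, dh_mask):
        img = optics.psf_at(dh_mask, 0.0, config, 160.0, 64, max_clip=None,
                            normalize="sum")
        assert img.sum() == pytest.approx(1.0, abs=1e-6)
        assert img.min() >= 0.0

    def test_energy_conserved_across_dh_range(self, config, dh_mask):
        sums = [
            optics.psf_at(dh_mask, z, config, 160.0, 128, max_clip=None).sum()
            for z in (-1.0, -0.5, 0.0, 0.5, 1.0)
        ]
        assert (max(sums) - min(sums)) / max(sums) < 0.01

    def test_lateral_shift_moves_image(self, config):
        clear = optics.build_mask("clear", config=config)
        img = optics.psf_at(clear, 0.0, config, 160.0, 32,
                            shift_nm=(320.0, 480.0), max_clip=None)
        iy, ix = np.unravel_index(np.argmax(img), img.shape)
        assert (iy - 16, ix - 16) == (3, 2)

    def test_energy_clip_guard(self, config, tp_mask):
        with pytest.raises(ValueError, match="clip"):
            optics.psf_at(tp_mask, 3.0, config, 160.0, 16)

    def test_z_beyond_twice_range_rejected(self, config, dh_mask):
        with pytest.raises(ValueError, match="range"):
            optics.psf_at(dh_mask, 4.5, config)


class TestDHAngleCurve:
    def test_monotone_rotation_under_half_turn(self, config, dh_mask):
        z = np.linspace(-1.0, 1.0, 11)
        curve = optics.dh_angle_curve(dh_mask, z, config)
        d = np.diff(curve.angle_deg.to_numpy())
        assert np.all(d > 0) or np.all(d < 0)
        assert curve.angle_deg.max() - curve.angle_deg.min() < 180.0
        # z = 0 is the reference orientation
        assert curve.angle_deg[np.argmin(np.abs(z))] == pytest.approx(0.0)

    def test_reversed_grid_same_pairs(self, config, dh_mask):
        z = np.linspace(-0.6, 0.6, 7)
        a = optics.dh_angle_curve(dh_mask, z, config)
        b = optics.dh_angle_curve(dh_mask, z[::-1], config)
        merged = a.merge(b, on="z_um", suffixes=("_f", "_r"))
        assert np.allclose(merged.angle_deg_f, merged.angle_deg_r, atol=1e-6)

    def test_opposite_defocus_opposite_rotation(self, config, dh_mask):
        z = np.array([-0.6, 0.0, 0.6])
        curve = optics.dh_angle_curve(dh_mask, z, config)
        a = curve.set_index("z_um").angle_deg
        assert a[-0.6] * a[0.6] < 0
        assert abs(a[-0.6] + a[0.6]) < 2.0  # antisymmetric within lobe-find noise

    def test_requires_dh_mask(self, config):
        clear = optics.build_mask("clear", config=config)
        with pytest.raises(ValueError):
            optics.dh_angle_curve(clear, [0.0, 0.5], config)


class TestCRLB:
    def test_inverse_sqrt_photon_scaling(self, config, dh_mask):
        b1 = optics.crlb(dh_mask, 1000.0, 0.0, 0.3, config)
        b4 = optics.crlb(dh_mask, 4000.0, 0.0, 0.3, config)
        for k in ("x_nm", "y_nm", "z_nm"):
            assert b1[k] / b4[k] == pytest.approx(2.0, rel=0.01)

    def test_clear_aperture_has_no_focal_z_information(self, config):
        clear = optics.build_mask("clear", config=config)
        b = optics.crlb(clear, 3000.0, 0.0, 0.0, config)
        assert np.isinf(b["z_nm"])
        assert np.isfinite(b["x_nm"])

    def test_dh_z_bound_uniform_across_range(self, config, dh_mask):
        bounds = [
            optics.crlb(dh_mask, 3000.0, 0.0, z, config)["z_nm"]
            for z in (-1.0, -0.5, 0.0, 0.5, 1.0)
        ]
        assert max(bounds) / min(bounds) < 2.0

    def test_input_validation(self, config, dh_mask):
        with pytest.raises(ValueError):
            optics.crlb(dh_mask, 0.0, 0.0, 0.0, config)
        with pytest.raises(ValueError):
            optics.crlb(dh_mask, 100.0, -1.0, 0.0, config)
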