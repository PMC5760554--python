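"""Shared fixtures: expensive calibrations built once per session."""

import numpy as np
import pytest

from tilt3d import dhloc, optics, tetrapod


@pytest.fixture(scope="session")
def config():
    return optics.OpticalConfig()


@pytest.fixture(scope="session")
def dh_mask(config):
    return optics.build_mask("double_helix", 2.0, config=config)


@pytest.fixture(scope="session")
def dh_calibration(config, dh_mask):
    """Bead-scan angle/separation calibration of the shipped 2 µm DH mask."""
    z = np.arange(-1.1, 1.1001, 0.05)
    stack = optics.render_stack(
        dh_mask, z, config, dx_nm=config.effective_pixel_nm, n_pixels=32,
        max_clip=None,
    )
    return dhloc.calibrate_dh(stack)


@pytest.fixture(scope="session")
def dh_template_model(config, dh_mask):
    """Fine-grid PSF templates for the maximum-likelihood polish."""
    return dhloc.TemplateModel(dh_mask, config, -1.05, 1.05, 0.03, 25)


@pytest.fixture(scope="session")
def tp_mask(config):
    return optics.build_mask("tetrapod", 6.0, optics.PupilGrid(), config)


@pytest.fixture(scope="session")
def tp_calibration(config, tp_mask):
    """Phase-retrieved 6 µm tetrapod calibration from a synthetic bead scan."""
    grid = tp_mask.grid
    px_native = tetrapod.native_pixel_nm(grid, config)
    z = np.arange(-3.0, 3.001, 0.25)
    stack = np.stack(
        [
            optics.psf_at(tp_mask, zi, config, px_native, grid.n_samples,
                          max_clip=None)
            for zi in z
        ]
    )
    return tetrapod.retrieve_pupil(stack, z, config, grid,
                                   template_range_um=(-3.5, 3.5))
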