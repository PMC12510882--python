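"""Shared fixtures: one optical configuration, sheet, ideal PSF and
embedding reference reused across the whole session."""

import numpy as np
import pytest

from fourierao.embedding import IdealReference
from fourierao.optics import (OpticalConfig, detection_psf, ideal_psf,
                              make_light_sheet, make_pupil, overall_psf)
from fourierao.simulator import CameraModel, PunctaField, render_volume
from fourierao.zernike import Wavefront


@pytest.fixture(scope="session")
def optics():
    return OpticalConfig()


@pytest.fixture(scope="session")
def sheet(optics):
    return make_light_sheet("gaussian", 1500.0, optics)


@pytest.fixture(scope="session")
def ideal(optics, sheet):
    return ideal_psf(optics, sheet)


@pytest.fixture(scope="session")
def reference(optics, ideal):
    return IdealReference.build(optics, ideal=ideal)


@pytest.fixture(scope="session")
def aberrated_psf(optics, sheet):
    """Factory: overall light-sheet PSF under a given wavefront."""

    def _make(wavefront=None):
        det = detection_psf(make_pupil(optics, wavefront))
        return overall_psf(det, sheet)

    return _make


@pytest.fixture(scope="session")
def centered_punctum(optics):
    """A single 100-nm punctum at the exact volume center."""
    D, H, W = optics.grid_shape
    return PunctaField(
        np.array([[D // 2 * optics.dz, H // 2 * optics.dy,
                   W // 2 * optics.dx]]),
        np.array([100.0]))


@pytest.fixture(scope="session")
def render_noisy(optics):
    """Factory: render puncta through a PSF and add camera noise."""

    def _render(puncta, psf, photons, seed=0):
        i_photon, _, _ = render_volume(puncta, psf, photons, optics)
        rng = np.random.default_rng(seed)
        from fourierao.simulator import apply_camera
        return apply_camera(i_photon, CameraModel(), rng)

    return _render
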