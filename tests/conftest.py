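"""Shared fixtures: beams, detectors, maps and noiseless preset frames.

Everything is generated programmatically; expensive session-scoped objects
(512x512 maps, noiseless frames) are shared across test modules.
"""

import numpy as np
import pytest
from hypothesis import settings

from celltex import BeamSpec, DetectorGeometry, build_qchi_map

settings.register_profile("reproducible", derandomize=True)
settings.load_profile("reproducible")
from celltex.simulate import default_detector, render_giwaxs, scene_presets


@pytest.fixture(scope="session")
def beam10():
    return BeamSpec(energy_kev=10.0, incidence_deg=0.15)


@pytest.fixture(scope="session")
def geometry512():
    return default_detector()


@pytest.fixture(scope="session")
def qcmap512(geometry512, beam10):
    return build_qchi_map(geometry512, beam10)


@pytest.fixture(scope="session")
def geometry_small():
    """Quarter-resolution detector with the same q coverage as the default."""
    return DetectorGeometry(
        distance_mm=120.0,
        pixel_mm=0.688,
        beam_center=(125.5, 64.0),
        shape=(128, 128),
    )


@pytest.fixture(scope="session")
def qcmap_small(geometry_small, beam10):
    return build_qchi_map(geometry_small, beam10)


@pytest.fixture(scope="session")
def unextracted_frame(geometry512, beam10):
    """Noiseless GIWAXS frame of the full specimen scene."""
    return render_giwaxs(
        scene_presets("unextracted"), geometry512, beam10, noiseless=True
    )


@pytest.fixture(scope="session")
def theta_bragg_110(beam10):
    """Half scattering angle of the cellulose 110 band center (q=1.15)."""
    return float(np.degrees(np.arcsin(1.15 / (2.0 * beam10.k_a))))
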