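import numpy as np
import pytest

from multiplane25d import OpticalConfig, NoiseModel, SplitterConfig
from multiplane25d import workflows as wf


@pytest.fixture(scope="session")
def optics_small():
    """Reduced pupil grid: same physics, faster transforms."""
    return OpticalConfig(pupil_grid_n=256)


@pytest.fixture(scope="session")
def noise_default():
    return NoiseModel()


@pytest.fixture(scope="session")
def scan_psf_small(optics_small):
    """Widefield rendering PSF covering +-8 um of defocus at 0.25 um steps."""
    return wf.make_scan_psf(optics_small, z_max=8.0, z_step=0.25,
                            crop_halfwidth=6.0)


@pytest.fixture(scope="session")
def focus_psf_small(optics_small):
    """Short-range widefield PSF for near-focus rendering."""
    return wf.make_scan_psf(optics_small, z_max=3.0, z_step=0.25,
                            crop_halfwidth=4.0)


@pytest.fixture(scope="session")
def splitter_300():
    return SplitterConfig(quadrant_shape_px=(300, 300),
                          sensor_shape_px=(600, 600))
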