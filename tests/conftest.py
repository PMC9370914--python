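import numpy as np
import pytest

from transillum3d.core import ImageGrid, OpticalProperties
from transillum3d import phantom, profiles


TISSUE = OpticalProperties(1.0, 0.01)

#: working scale of the 2D pipeline experiments: a 128 mm field at
#: 0.5 mm/px keeps the PSF's ~60 mm scattering halo inside the image
STACK_GRID = ImageGrid(256, 256, 0.5)
STACK_KERNEL_CAP = (256 // 2 - 1) * 0.5


@pytest.fixture(scope="session")
def optics():
    return TISSUE


@pytest.fixture(scope="session")
def small_lut(optics):
    """Coarse lookup table (depth 2-6, diameter 2-4, 0.5 mm steps) for
    fast unit tests of the inversion machinery."""
    return profiles.build_lookup_table((2.0, 6.0), (2.0, 4.0), 0.5,
                                       optical=optics)


@pytest.fixture(scope="session")
def bar_image(optics):
    """Noise-free blurred image of a full-height 3 mm cylinder at 5 mm
    depth on the 2D working grid."""
    p = phantom.make_cylinder_phantom(3.0, 140, 0, 5.0, 5.0, STACK_GRID,
                                      top_row_mm=-1.0)
    img = phantom.blur_image(p, optics,
                             max_kernel_radius_mm=STACK_KERNEL_CAP)
    return p, img
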