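import numpy as np
import pytest

from nanofoci.render import GridSpec, NucleusROI, disc_cluster_set


@pytest.fixture
def square_roi():
    """A 4 x 4 um square ROI with its lower-left corner at the origin."""
    return NucleusROI(polygon=[(0.0, 0.0), (4000.0, 0.0), (4000.0, 4000.0), (0.0, 4000.0)])


@pytest.fixture
def square_grid(square_roi):
    return square_roi.default_grid(20.0)


def make_disc_set(centers, radii, grid, channel="A", roi=None):
    return disc_cluster_set(np.atleast_2d(centers), np.atleast_1d(radii), grid, channel, roi=roi)
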