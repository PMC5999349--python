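import numpy as np
import pytest
from hypothesis import settings

from rtdcstats import Contour, gen_contour

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def circle_360():
    """360-gon approximation of a circle, radius 10 px."""
    return gen_contour("circle", radius=10.0, n_vertices=360)


@pytest.fixture
def unit_square():
    return Contour(np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]))


@pytest.fixture
def ellipse_8_4():
    """x-aligned ellipse, semi-axes a=8 (flow), b=4."""
    return gen_contour("ellipse", a=8.0, b=4.0, n_vertices=720)


@pytest.fixture
def star_5():
    """5-point star: strongly non-convex."""
    return gen_contour("star", radius=10.0, n_spikes=5)
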