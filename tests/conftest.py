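import numpy as np
import pytest

from filanet import phantom
from filanet.imgio import Volume, rescale


@pytest.fixture(scope="session")
def rod_gt():
    """A single straight rod along x in a 64^3 box."""
    pts = phantom.densify(np.array([[12.0, 32.0, 32.0], [52.0, 32.0, 32.0]]), 1.0)
    return phantom.GroundTruth([pts], (64, 64, 64))


@pytest.fixture(scope="session")
def rod_volume(rod_gt):
    """Noiseless rendering of the single rod (peak-normalized kernel)."""
    spec = phantom.PhantomSpec(kernel_norm="peak", noise_model="none")
    return rescale(phantom.render(rod_gt, spec))


@pytest.fixture(scope="session")
def crossing_gt():
    """Two rods crossing at 90 degrees in a thin 3D slab."""
    return phantom.make_crossing_rods((64, 64, 16))


@pytest.fixture(scope="session")
def crossing_volume(crossing_gt):
    spec = phantom.PhantomSpec(
        kernel_norm="peak", noise_model="none", psf_sigma=(1.73, 1.73, 1.73)
    )
    return rescale(phantom.render(crossing_gt, spec))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
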