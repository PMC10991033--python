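import numpy as np
import pytest

from envmra import MRAModel, TissuePhantomSpec, simulate_frame


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def three_component_model() -> MRAModel:
    """A well-separated normalized 3-component mixture (power ratio 6)."""
    return MRAModel(scales=(0.25, 1.0, 6.0), rates=(0.2, 0.6, 0.2)).normalized()


@pytest.fixture(scope="session")
def healthy_frame():
    """One homogeneous fully-developed-speckle frame (PSF on)."""
    return simulate_frame(TissuePhantomSpec.healthy(), seed=101)


@pytest.fixture(scope="session")
def fibrotic_frame():
    return simulate_frame(TissuePhantomSpec.fibrotic(), seed=101)
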