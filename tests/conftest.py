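import numpy as np
import pytest

from zincolor import CircuitParams, OpticalModel, simulate_assay_images


@pytest.fixture
def params():
    return CircuitParams()


@pytest.fixture
def noiseless_optics():
    return OpticalModel(noise_sigma=0.0)


@pytest.fixture
def noisy_optics():
    return OpticalModel(noise_sigma=3.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def noiseless_assay(noiseless_optics):
    """One noiseless simulated six-tube assay: standards {0,1,2,3.5,5}, test 2.5."""
    image, table = simulate_assay_images(
        standards_zinc=[0.0, 1.0, 2.0, 3.5, 5.0],
        test_zinc=2.5,
        optics=noiseless_optics,
        seed=7,
    )
    return image, table
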