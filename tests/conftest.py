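import numpy as np
import pytest

from sparsepitch import experiments as ex
from sparsepitch.periphery import PeripheryConfig


@pytest.fixture(scope="session")
def desk_pipeline():
    """Shared desk-scale pipeline (M=250 tone atoms at 30 dB, linear periphery).

    Dictionary and sieve construction is memoised inside the package, so every
    test that asks for the same build parameters reuses one instance.
    """
    return ex.make_pipeline(preset="desk")


@pytest.fixture(scope="session")
def tiny_periphery():
    """A fast low-channel periphery for stimulus-level unit tests."""
    return PeripheryConfig(n_channels=40, downsample=2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
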