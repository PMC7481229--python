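import pytest

from dropjet import EUXFEL, FLUID_PFD_PFO


@pytest.fixture(scope="session")
def fluid():
    """The studied fluid pair / T-junction geometry preset."""
    return FLUID_PFD_PFO


@pytest.fixture(scope="session")
def euxfel():
    """EuXFEL early-user pulse schedule."""
    return EUXFEL.schedule
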