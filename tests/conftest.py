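import numpy as np
import pytest

from mlsail.optical_constants import standard_constants, synthetic_constants


@pytest.fixture(scope="session")
def std_constants():
    return standard_constants()


@pytest.fixture(scope="session")
def syn_constants():
    return synthetic_constants()


@pytest.fixture(scope="session")
def probe_wavelengths():
    """Small wavelength set spanning visible, NIR and SWIR for fast canopy runs."""
    return np.array([450.0, 560.0, 685.0, 810.0, 970.0, 1450.0, 1940.0, 2200.0])
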