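import numpy as np
import pytest

from fibrilwater.qens import ResolutionModel


@pytest.fixture(scope="session")
def e_grid():
    """Uniform +/-100 ueV energy grid, 0.5 ueV step."""
    return np.arange(-100.0, 100.25, 0.5)


@pytest.fixture(scope="session")
def resolution():
    """Backscattering-like Gaussian resolution, 3.5 ueV FWHM."""
    return ResolutionModel(fwhm=3.5)


@pytest.fixture(scope="session")
def analysis_q():
    """Default per-Q analysis set below the coherent-contamination region."""
    return np.arange(0.3, 0.95, 0.1)
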