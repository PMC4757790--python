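import numpy as np
import pytest

from znpp.core_io import Spectrum, default_grid
from znpp.references import load_reference_library


@pytest.fixture(scope="session")
def refs():
    return load_reference_library()


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture
def make_spectrum(grid):
    """Factory for calibrated/raw spectra on the default grid."""

    def _make(intensity, excitation_nm=425, t_ms=200.0, calibrated=False):
        intensity = np.broadcast_to(np.asarray(intensity, float), (len(grid),))
        return Spectrum(
            grid=grid,
            intensity=np.array(intensity),
            excitation_nm=excitation_nm,
            integration_time_ms=t_ms,
            calibrated=calibrated,
        )

    return _make
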