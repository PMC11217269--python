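import numpy as np
import pytest

from icealgae.bands import default_band_registry, registry_by_name
from icealgae.spectra import Spectrum


@pytest.fixture(scope="session")
def registry():
    return default_band_registry()


@pytest.fixture(scope="session")
def bands_by_name(registry):
    return registry_by_name(registry)


@pytest.fixture
def grid():
    """Acquisition grid: 4000 down to 800 cm^-1 at 4 cm^-1 steps."""
    return np.arange(4000.0, 799.0, -4.0)


@pytest.fixture
def raw_spectrum(grid):
    def _make(values=None, stage="raw", **meta):
        if values is None:
            values = np.zeros_like(grid)
        return Spectrum(wavenumbers=grid, absorbance=values, stage=stage, **meta)

    return _make
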