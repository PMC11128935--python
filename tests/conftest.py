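import numpy as np
import pytest

from plastscreen import Spectrum, SpectrumSet


@pytest.fixture
def uniform_grid():
    """4 cm^-1 FTIR working grid."""
    return 400.0 + 4.0 * np.arange(901)


@pytest.fixture
def gaussian_spectrum(uniform_grid):
    """Single Gaussian band at 1715 cm^-1, FWHM 20, on zero baseline."""
    sigma = 20.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    y = np.exp(-0.5 * ((uniform_grid - 1715.0) / sigma) ** 2)
    return Spectrum(uniform_grid, y)


def make_set(grid, rows, **meta):
    """SpectrumSet from a 2-D intensity array."""
    return SpectrumSet(tuple(Spectrum(grid, r, **meta) for r in np.atleast_2d(rows)), grid=grid)
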