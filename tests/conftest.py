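import numpy as np
import pytest

from hyperfod.cube_io import CalibrationPair, Hypercube, default_wavelength_grid
from hyperfod.taxonomy import default_taxonomy


@pytest.fixture
def taxonomy():
    return default_taxonomy()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_raw_cube(rng, lines=24, samples=32, low=100.0, high=4000.0):
    """A small random raw cube on the default 224-band grid."""
    data = rng.uniform(low, high, size=(lines, samples, 224)).astype(np.float32)
    return Hypercube(
        data=data,
        wavelengths=default_wavelength_grid(),
        state="raw224",
        meta={"temperature": 25.0},
    )


def make_pair(rng, samples=32, n_bands=224):
    dark = rng.uniform(80, 110, size=(samples, n_bands))
    flat = dark + rng.uniform(1500, 3000, size=(samples, n_bands))
    return CalibrationPair(dark=dark, flat=flat, temperature=25.0)


@pytest.fixture
def raw_cube(rng):
    return make_raw_cube(rng)


@pytest.fixture
def calib_pair(rng):
    return make_pair(rng)
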