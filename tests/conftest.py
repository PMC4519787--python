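import numpy as np
import pytest

import stainsim as ss


@pytest.fixture(scope="session")
def grid():
    return ss.DEFAULT_GRID


@pytest.fixture(scope="session")
def wideband():
    return ss.wideband_system()


@pytest.fixture(scope="session")
def led():
    return ss.sequential_led_system()


@pytest.fixture(scope="session")
def mono():
    return ss.monochromatic_system()


@pytest.fixture(scope="session")
def dab():
    return ss.catalogue_stain("DAB")


@pytest.fixture(scope="session")
def htx():
    return ss.catalogue_stain("HTX")


@pytest.fixture(scope="session")
def wideband_surface(wideband, dab, htx):
    """B/G-plane error surface of the DAB/HTX pair under wideband light."""
    return ss.error_surface(wideband, (dab, htx))


@pytest.fixture(scope="session")
def led_surface(led, dab, htx):
    return ss.error_surface(led, (dab, htx))


def random_stain(rng, name="stain", grid=ss.DEFAULT_GRID):
    """A random, strictly positive optical-density spectrum."""
    od = ss.Spectrum(grid, rng.uniform(0.05, 1.0, grid.n), "optical_density")
    return ss.StainDefinition(name, od)
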