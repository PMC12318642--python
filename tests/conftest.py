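import numpy as np
import pytest

import polspec as ps


@pytest.fixture(scope="session")
def grid():
    return ps.default_grid()


@pytest.fixture(scope="session")
def config():
    return ps.InstrumentConfig()


@pytest.fixture(scope="session")
def mods():
    return ps.ModulationSet()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_spectrum(rng, grid, smooth=True):
    """Random non-negative spectrum; smooth ones via squared random cosines."""
    lam = grid.wavelengths_nm
    if smooth:
        inten = np.zeros_like(lam)
        for _ in range(4):
            f = rng.uniform(0.5, 4.0)
            ph = rng.uniform(0, 2 * np.pi)
            inten += rng.uniform(0.2, 1.0) * (
                1 + np.cos(2 * np.pi * f * (lam - lam[0]) / (lam[-1] - lam[0]) + ph)
            )
    else:
        inten = rng.uniform(0, 1, size=lam.size)
    return ps.Spectrum(grid, inten)
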