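import numpy as np
import pandas as pd
import pytest

from vitispec.grid import build_grid, canonical_grid
from vitispec.simulate import default_design, default_noise, generate_dataset
from vitispec.spectra import SpectralLibrary, Spectrum, aggregate


@pytest.fixture(scope="session")
def grid():
    return canonical_grid()


@pytest.fixture
def flat_spectrum(grid):
    return Spectrum(grid, np.full(len(grid), 0.5), "flat")


@pytest.fixture
def random_spectrum(grid):
    rng = np.random.default_rng(42)
    return Spectrum(grid, rng.uniform(0.05, 0.95, len(grid)), "random")


def make_library(grid, values, pots=None):
    """Helper: library from a (n, channels) array with minimal metadata."""
    values = np.atleast_2d(values)
    n = values.shape[0]
    pots = pots or [f"P{i}" for i in range(n)]
    meta = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "pot_id": pots,
        "metal": ["none"] * n,
        "level": ["C"] * n,
        "replicate": [1] * n,
        "leaf": list(range(1, n + 1)),
    })
    return SpectralLibrary(grid, values, meta)


@pytest.fixture(scope="session")
def default_dataset():
    """The default 84-pot / 420-spectra synthetic experiment, seed 7."""
    design = default_design()
    library, conc = generate_dataset(design, noise=default_noise(seed=7))
    return design, library, conc


@pytest.fixture(scope="session")
def pot_library(default_dataset):
    _, library, _ = default_dataset
    return aggregate(library, "pot")


@pytest.fixture
def small_grid():
    return build_grid(400, 409, 1)
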