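import numpy as np
import pytest

from saffronir import SpectraSet, WavelengthGrid
from saffronir.simulate import default_config, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spectra(rng) -> SpectraSet:
    """10 random spectra on a 50-point grid, guaranteed non-constant rows."""
    grid = WavelengthGrid(np.linspace(1000.0, 2470.0, 50))
    X = rng.normal(0.8, 0.1, size=(10, 50)) + np.linspace(0, 0.3, 50)
    return SpectraSet([f"S{i}" for i in range(10)], grid, X)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small synthetic dataset shared across tests (120 samples, full grid)."""
    cfg = default_config(n_samples=120, seed=7)
    return generate(cfg)
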