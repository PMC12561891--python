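import numpy as np
import pytest

from oleanir import GeneratorConfig, SpectraSet
from oleanir.simulate import generate_dataset, generate_profiles


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Compact study-shaped configuration for fast end-to-end tests."""
    return GeneratorConfig(n_samples=30, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def default_profiles():
    return generate_profiles(GeneratorConfig(seed=1))


@pytest.fixture()
def toy_spectra() -> SpectraSet:
    """5 spectra x 20 wavelengths, reproducible random absorbance."""
    rng = np.random.default_rng(42)
    wavenumbers = np.arange(5000.0, 4920.0, -4.0)
    return SpectraSet(
        wavenumbers=wavenumbers,
        absorbance=rng.uniform(0.1, 1.0, size=(5, wavenumbers.size)),
    )
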