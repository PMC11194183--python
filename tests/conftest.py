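import numpy as np
import pytest

from pteroshell import GeneratorConfig, seasonal_treatment_chemistry


@pytest.fixture(scope="session")
def chemistry_table():
    return seasonal_treatment_chemistry()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_config():
    """Generator config kept small for fast unit tests."""
    return GeneratorConfig(seed=7, n_genes=400, n_strong=40, n_very_strong=8)
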