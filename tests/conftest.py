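import numpy as np
import pytest

from aggsim_cea import load_study_table, load_utility_profile


@pytest.fixture(scope="session")
def table1():
    """The bundled ten-trial study table."""
    return load_study_table()


@pytest.fixture(scope="session")
def coefficients():
    """The bundled synthetic placeholder utility profile."""
    return load_utility_profile("placeholder")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
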