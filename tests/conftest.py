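import numpy as np
import pytest

from warmsoil import synthetic as syn


@pytest.fixture(scope="session")
def small_config() -> syn.SyntheticConfig:
    """Two blocks over four years: fast enough for end-to-end chains."""
    return syn.SyntheticConfig(seed=11, n_blocks=2, years=(2005, 2008))


@pytest.fixture(scope="session")
def bomb_curve():
    return syn.synth_atmospheric_curve()


@pytest.fixture(scope="session")
def topsoil_model():
    """Study-condition three-pool model for the control topsoil."""
    return syn.default_radiocarbon_model("control", "0-10")


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
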