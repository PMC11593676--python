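import numpy as np
import pytest

from steroidomics import SimulationDesign, default_catalog, simulate


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def demo_dataset():
    """One default synthetic cohort (25 patients / 15 controls, planted
    5-up / 15-down effects) shared across tests."""
    return simulate(SimulationDesign(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
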