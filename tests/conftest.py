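import numpy as np
import pytest

from chondrosim.fixtures import FixtureSpec, make_depth_profile_fixture, paper_like_strain_field
from chondrosim.scenarios import ScenarioConfig


@pytest.fixture(scope="session")
def reference_strain_field():
    """Synthetic strain field encoding the reference impact outcome."""
    return paper_like_strain_field(FixtureSpec())


@pytest.fixture(scope="session")
def scenario_config():
    return ScenarioConfig()


@pytest.fixture(scope="session")
def depth_profile():
    return make_depth_profile_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
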