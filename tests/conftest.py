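import numpy as np
import pytest

from erpgan.datasets import ChannelLayout
from erpgan.simulate import make_fixture_cohort, make_scenario


@pytest.fixture(scope="session")
def layout8() -> ChannelLayout:
    return ChannelLayout.standard()


@pytest.fixture(scope="session")
def paper_like_cohort():
    """40-subject paper-like cohort used by several statistics tests."""
    return make_fixture_cohort("paper_like", n_subjects=40, seed=11)


@pytest.fixture(scope="session")
def small_scenario():
    return make_scenario("paper_like", n_subjects=6, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
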