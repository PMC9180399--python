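import numpy as np
import pytest

import saladm as sa
from saladm.reactor import compile_model


@pytest.fixture(scope="session")
def nacl_model():
    return compile_model(sa.build_model("NaCl"))


@pytest.fixture(scope="session")
def sulfate_model():
    return compile_model(sa.build_model("Na2SO4_NaHCO3"))


@pytest.fixture(scope="session")
def nacl_steady(nacl_model):
    """Converged NaCl reactor at the final reported operating point."""
    return sa.steady_state(nacl_model, olr=0.75, srt=40.0)


@pytest.fixture(scope="session")
def sulfate_steady(sulfate_model):
    """Converged sulfate-salt reactor at the overall loading of the run."""
    return sa.steady_state(sulfate_model, olr=0.39, srt=40.0,
                           sulfate_feed=0.245)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
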