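import warnings

import numpy as np
import pytest

from riskephys.core import exclude_shock_trials
from riskephys.synth import GeneratorConfig, generate_session, null_config

warnings.filterwarnings("ignore", message="GPFA EM did not converge")


@pytest.fixture(scope="session")
def coupled_session():
    """Default synthetic session: all block effects on."""
    return generate_session(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def null_session():
    """No-shock control: every block effect off."""
    return generate_session(null_config(seed=12))


@pytest.fixture(scope="session")
def coupled_trials(coupled_session):
    return exclude_shock_trials(coupled_session.trials)


@pytest.fixture(scope="session")
def null_trials(null_session):
    return exclude_shock_trials(null_session.trials)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
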