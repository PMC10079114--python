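import numpy as np
import pytest

from threatdyn.sweep import ParameterSweep, default_sweep_design
from threatdyn.synthetic import default_config, generate_survey


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_survey():
    """A modest survey table for unit-level checks."""
    return generate_survey(default_config(n_respondents=400, seed=0))


@pytest.fixture(scope="session")
def full_survey():
    """The default-size table emulating the deposited file."""
    return generate_survey(default_config(seed=1))


@pytest.fixture(scope="session")
def default_sweep():
    """The full default 20,000-run sweep (pinned design seed)."""
    return ParameterSweep(default_sweep_design()).run().table


@pytest.fixture(scope="session")
def small_sweep():
    """A 2,000-run sweep for cheaper distributional checks."""
    return ParameterSweep(default_sweep_design(n_sets=2000, seed=3)).run().table
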