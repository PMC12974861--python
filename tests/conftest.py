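import pytest
from hypothesis import settings

import agridiff as ag

settings.register_profile("default", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("default")


@pytest.fixture(scope="session")
def base_config():
    return ag.preset("base")


@pytest.fixture(scope="session")
def base_trajectory(base_config):
    return ag.simulate(base_config)


@pytest.fixture(scope="session")
def base_ledger(base_trajectory):
    return ag.build_ledger(base_trajectory)


@pytest.fixture(scope="session")
def base_summary(base_trajectory, base_ledger):
    return ag.summarize(base_trajectory, base_ledger)
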