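import pytest
from hypothesis import settings

from zooencounter import (BootstrapConfig, default_scenarios, packaged_fixtures,
                          taxon_registry)

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def registry():
    return taxon_registry()


@pytest.fixture(scope="session")
def fixtures():
    return packaged_fixtures()


@pytest.fixture(scope="session")
def scenarios():
    return default_scenarios()


@pytest.fixture
def small_bootstrap():
    return BootstrapConfig(n_reps=300, seed=7)
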