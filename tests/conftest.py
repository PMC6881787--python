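import pytest
from hypothesis import settings

from rhizotrial.anova import FactorialAnova
from rhizotrial.simulate import (
    jar_config,
    pot_config,
    simulate_null_batch,
    simulate_trial,
)

settings.register_profile("suite", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def jar_records():
    """One simulated Leonard-jar screening (500 units) under default conditions."""
    return simulate_trial(jar_config(seed=11))


@pytest.fixture(scope="session")
def pot_records():
    """One simulated pot confirmation (200 units, with shoot %N)."""
    return simulate_trial(pot_config(seed=13))


@pytest.fixture(scope="session")
def jar_anova(jar_records):
    return FactorialAnova(response="sdw").fit(jar_records)


@pytest.fixture(scope="session")
def null_batch():
    """500 jar-design simulations with a purely additive truth."""
    cfg = jar_config(interaction_rank=0, singular_values=())
    return simulate_null_batch(cfg, n_runs=500, seed=202)
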