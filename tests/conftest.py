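import pytest

from basketintake.pipeline import RunConfig, run
from basketintake.simulate import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A small but fully featured synthetic world shared across tests.

    Out-of-period trip density is reduced for speed; out-of-period
    lines never enter any statistic computed over the comparison
    period.
    """
    return GeneratorConfig(seed=7, n_participants=80, out_of_period_trips_per_week=0.3)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_report(small_config):
    return run(RunConfig(generator=small_config))
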