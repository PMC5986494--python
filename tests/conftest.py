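import pytest

from fopl_cea import pipeline
from fopl_cea.config import RunConfig, SyntheticConfig
from fopl_cea.synthetic_data import generate_dataset


@pytest.fixture(scope="session")
def dataset():
    """Reference synthetic dataset at the shipped fixture seed."""
    return generate_dataset(SyntheticConfig())


@pytest.fixture(scope="session")
def voluntary_bundle(dataset):
    """Voluntary-scenario run with a scaled-down 200-iteration PSA."""
    cfg = RunConfig(scenario="voluntary", n_iter=200, seed=7)
    return pipeline.run_scenario(dataset, cfg)


@pytest.fixture(scope="session")
def voluntary_point(dataset):
    cfg = RunConfig(scenario="voluntary")
    return pipeline.run_scenario(dataset, cfg, run_uncertainty=False)


@pytest.fixture(scope="session")
def mandatory_point(dataset):
    cfg = RunConfig(scenario="mandatory")
    return pipeline.run_scenario(dataset, cfg, run_uncertainty=False)
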