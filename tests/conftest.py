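import numpy as np
import pytest

from droptox import GeneratorConfig, PipelineConfig, generate_experiment, run_pipeline


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Two 512 px tiles, four hourly frames — enough droplets (~130) to
    exercise every stage quickly."""
    return GeneratorConfig(n_tiles=2, n_timepoints=4, seed=11)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return generate_experiment(small_config)


@pytest.fixture(scope="session")
def small_run(small_experiment):
    stack, truth = small_experiment
    result = run_pipeline(stack, PipelineConfig())
    return result, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
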