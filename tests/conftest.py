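import numpy as np
import pytest

from sclerheo import birefringence as bf


@pytest.fixture(scope="session")
def bias_table():
    """One Monte-Carlo bias table shared across the suite (deterministic)."""
    return bf.build_bias_table(rng_seed=0)


@pytest.fixture(scope="session")
def default_config():
    return bf.PipelineConfig(rng_seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
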