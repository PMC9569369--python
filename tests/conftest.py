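import numpy as np
import pytest

from fundus_eval.synthetic import SynthConfig, generate_fundus

# One project-wide master seed, fixed up front for every stochastic check.
MASTER_SEED = 0


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """Desk-scale generator config used across the suite (256-px frame)."""
    return SynthConfig(image_size=256, seed=MASTER_SEED)


@pytest.fixture(scope="session")
def small_image_truth(small_config):
    return generate_fundus(small_config)


@pytest.fixture(scope="session")
def medium_image_truth():
    return generate_fundus(SynthConfig(image_size=512, seed=MASTER_SEED))


@pytest.fixture
def rng():
    return np.random.default_rng(MASTER_SEED)
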