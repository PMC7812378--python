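import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from activelisten.config import ModelConfig
from activelisten.fixtures import build_demo_lexicon

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config() -> ModelConfig:
    return ModelConfig()


@pytest.fixture(scope="session")
def demo_lexicon(config):
    """The 14-word demo lexicon, built once per session (seed 0)."""
    return build_demo_lexicon(seed=0, config=config)


@pytest.fixture(scope="session")
def small_lexicon(config):
    """A cheaper 5-word lexicon for unit tests."""
    labels = ("triangle", "square", "is", "above", "red")
    return build_demo_lexicon(labels, n_exemplars=4, seed=1, config=config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
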