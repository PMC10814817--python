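import numpy as np
import pytest

from disccascade.phantom import PhantomConfig, generate_sample


@pytest.fixture(scope="session")
def desk_cfg() -> PhantomConfig:
    return PhantomConfig.desk()


@pytest.fixture(scope="session")
def sample(desk_cfg):
    """One deterministic annotated phantom at desk scale."""
    return generate_sample(desk_cfg, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
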