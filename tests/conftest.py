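import math

import numpy as np
import pytest

from corneasim import build_tissue
from corneasim.engine import ModelConfig, build_tables


@pytest.fixture(scope="session")
def grid8():
    return build_tissue(8, 1)


@pytest.fixture(scope="session")
def grid31():
    return build_tissue(31, 1)


@pytest.fixture(scope="session")
def grid101():
    return build_tissue(101, 1)


@pytest.fixture(scope="session")
def tiny_tables():
    """Precomputed removal tables for a tiny unbiased coupled model."""
    cfg = ModelConfig(R_total=8, m=2, rls=None, model_class="coupled",
                      alpha=2 * math.pi)
    return cfg, build_tables(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
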