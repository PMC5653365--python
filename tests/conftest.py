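import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from octfluid import PipelineConfig, generate_bscan, make_spec


@pytest.fixture(scope="session")
def default_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free layered phantom with one intraretinal blob."""
    return generate_bscan(make_spec("intraretinal", rng_seed=7, speckle_L=None))


@pytest.fixture(scope="session")
def speckled_phantom():
    """Speckled phantom with mixed fluid types."""
    return generate_bscan(make_spec("mixed", rng_seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
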