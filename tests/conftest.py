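import numpy as np
import pytest

from riparia.covariates import build_stack
from riparia.grids import GridSpec
from riparia.synthetic import LandscapeConfig, generate_landscape

SEEDS = {k: 1 for k in ("landscape", "species", "surveys", "conflict", "households", "scenario")}


@pytest.fixture(scope="session")
def spec():
    return GridSpec(60, 60, resolution=30.0)


@pytest.fixture(scope="session")
def bundle(spec):
    return generate_landscape(spec, LandscapeConfig(), seed=1)


@pytest.fixture(scope="session")
def stack(bundle):
    return build_stack(bundle)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
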