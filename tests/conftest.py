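import numpy as np
import pytest

from pctchange import PairedSample, bp_heterogeneous, bp_proportional


@pytest.fixture
def bp_prop() -> PairedSample:
    return bp_proportional()


@pytest.fixture
def bp_het() -> PairedSample:
    return bp_heterogeneous()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160316)
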