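import numpy as np
import pytest

from epichain import NucleationLayout, RateParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_layout():
    """6-unit chain, one nucleation site per mark, non-overlapping."""
    return NucleationLayout(6, {1: [1], 2: [4]})


@pytest.fixture
def default_rates():
    return RateParams(p_a=0.2, p_d=0.2, p_s=[0.3, 0.3])
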