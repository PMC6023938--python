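import numpy as np
import pytest

from dcascape import CouplingModel


@pytest.fixture
def model_factory():
    """Random symmetric coupling models with zero self-blocks."""

    def make(L=6, q=4, seed=0, coupling_scale=0.5, field_scale=0.5):
        rng = np.random.default_rng(seed)
        e = rng.normal(0.0, coupling_scale, size=(L, L, q, q))
        e = (e + e.transpose(1, 0, 3, 2)) / 2
        e[np.arange(L), np.arange(L)] = 0.0
        h = rng.normal(0.0, field_scale, size=(L, q))
        return CouplingModel(couplings=e, fields=h, gauge_tag="test")

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
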