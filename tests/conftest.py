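import numpy as np
import pytest

from verdure.backbone import BackboneConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_config():
    """Smallest valid backbone: C=24, one block pair per stage, 2-token windows."""
    return BackboneConfig(embed_dim=24, depths=(2, 2, 2, 2),
                          heads=(2, 2, 4, 4), window_size=2)


@pytest.fixture
def f64():
    """Run a test in float64 for finite-difference headroom."""
    from verdure.nn.tensor import get_default_dtype, set_default_dtype

    previous = get_default_dtype()
    set_default_dtype(np.float64)
    yield
    set_default_dtype(previous)
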