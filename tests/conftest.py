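import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_unit_rows(rng, t, m):
    x = rng.standard_normal((t, m))
    return x / np.linalg.norm(x, axis=1, keepdims=True)
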