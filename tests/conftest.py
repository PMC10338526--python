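import numpy as np
import pytest

from pallidoseek import DffParams, DffTrace


def make_dff(values, fps=30.0, params=None):
    """Wrap a plain array as a DffTrace for alignment/decoding tests."""
    return DffTrace(fps=fps, dff=np.asarray(values, dtype=float),
                    params=params or DffParams())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
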