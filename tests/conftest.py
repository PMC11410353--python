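import numpy as np
import pytest

import oddwave as ow


@pytest.fixture(scope="session")
def grid64():
    return ow.make_layout("grid64")


@pytest.fixture()
def chain4():
    return ow.make_layout("chain-4")


@pytest.fixture()
def mesh12():
    return ow.make_layout("mesh-3x4")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_epochs(data, layout, times=None, metadata=None):
    """Wrap a raw (trials, channels, samples) array into an EpochArray."""
    import pandas as pd

    data = np.asarray(data, dtype=float)
    n, ch, s = data.shape
    if times is None:
        times = np.arange(-150, -150 + s, dtype=float)
    if metadata is None:
        metadata = pd.DataFrame({
            "participant": ["p0"] * n,
            "block": [0] * n,
            "block_type": ["+asp"] * n,
            "contrast": ["vot"] * n,
            "trial": range(n),
            "role": ["standard"] * n,
            "segment": ["pseudorandom"] * n,
            "token": ["ba"] * n,
            "analyzable": [True] * n,
            "true_effect": [0.0] * n,
            "artifact": [False] * n,
        })
    return ow.EpochArray(data=data, times=np.asarray(times, float),
                         metadata=metadata, layout=layout)
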