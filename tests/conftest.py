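import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_quantities(rng):
    """4 genes x 6 samples of positive relative quantities."""
    q = rng.lognormal(0.0, 0.4, size=(6, 4))
    return pd.DataFrame(
        q, index=[f"s{i}" for i in range(6)], columns=list("ABCD")
    )


@pytest.fixture
def toy_cq(rng):
    """3 genes x 8 samples of plausible adjusted Cq values."""
    cq = rng.normal(25.0, 1.0, size=(8, 3))
    return pd.DataFrame(
        cq, index=[f"s{i}" for i in range(8)], columns=list("XYZ")
    )
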