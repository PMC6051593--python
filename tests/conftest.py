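import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from statseq import build_model


@pytest.fixture(scope="session")
def models():
    """The three canonical stimulus models, keyed by level."""
    return {lvl: build_model(lvl) for lvl in (0, 1, 2)}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
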