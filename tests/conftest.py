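import numpy as np
import pytest

from mmpscreen import fixtures as fx


@pytest.fixture(scope="session")
def small_classification_set():
    """60/60 scaffold-actives vs ester decoys, enough for 5-fold CV."""
    return fx.make_classification_set(60, 60, seed=0)


@pytest.fixture(scope="session")
def charged_pose():
    return fx.make_charged_pose(5, "random", seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
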