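import numpy as np
import pytest

import beltsense as bs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def walk_signals():
    """Derived signals of a 10 s walking bout (15 windows)."""
    rec = bs.generate_activity("walk", 10.0, seed=7)
    return bs.derive_signals(rec)


@pytest.fixture(scope="session")
def small_dataset():
    """5 heterogeneous subjects x 7 activities, ~12.8 s bouts (665 windows)."""
    return bs.generate_dataset(n_subjects=5, duration_per_activity=12.8, seed=11)
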