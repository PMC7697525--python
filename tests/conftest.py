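import numpy as np
import pytest
from hypothesis import settings

import helixct as hx

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def gc_params():
    return hx.default_params("GC")


@pytest.fixture(scope="session")
def at_params():
    return hx.default_params("AT")


@pytest.fixture(scope="session")
def frame(gc_params):
    return hx.derive_frame(gc_params.geometry)


@pytest.fixture(scope="session")
def cf_gc(gc_params, frame):
    return hx.characteristic_frequencies(gc_params, frame)


@pytest.fixture(scope="session")
def cf_at(at_params, frame):
    return hx.characteristic_frequencies(at_params, frame)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20201113)
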