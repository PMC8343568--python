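import numpy as np
import pytest

from actfast import build_world


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic study shared by read-only tests."""
    return build_world(
        n_actions=60,
        n_trs=400,
        n_participants=3,
        n_voxels=80,
        n_reliable=40,
        temperature=0.3,
        concentration=0.6,
        noise_sd=0.3,
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
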