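import numpy as np
import pytest
from hypothesis import settings

from preplay.synthetic import SyntheticSpec, ellipsoid_mask

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def roi_mask():
    return ellipsoid_mask((8, 8, 8))


@pytest.fixture(scope="session")
def tiny_spec():
    """A cohort small enough for fast end-to-end runs."""
    return SyntheticSpec(
        n_subjects=2,
        n_prior=4,
        n_posterior=8,
        n_associated=4,
        n_associated_sd=0.0,
        roi_shape=(6, 6, 6),
        n_rest_frames=60,
        n_discard_frames=2,
        n_induced_sessions=2,
        reactivation_events_per_sentence=5,
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
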