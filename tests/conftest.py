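import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from conjradiomics.phantom import PhantomParams, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small rendered cohort shared by tests that only read it."""
    params = PhantomParams(
        n_participants=12, photos_per_eye_per_device=1,
        image_size=(64, 64), seed=7,
    )
    return params, *generate_cohort(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
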