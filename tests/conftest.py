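import numpy as np
import pytest

from voitools.models import (sample_gaussian_linear, sample_influenza,
                             savi_like_spec)

# fixed study seed used for the frozen reference datasets
STUDY_SEED = 20160518


@pytest.fixture(scope="session")
def savi_spec():
    return savi_like_spec()


@pytest.fixture(scope="session")
def savi_dataset(savi_spec):
    """Frozen 19-parameter Gaussian-linear PSA run, S = 1000."""
    return sample_gaussian_linear(savi_spec, S=1000, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def influenza_dataset():
    return sample_influenza(S=1000, seed=STUDY_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
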