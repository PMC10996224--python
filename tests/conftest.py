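import numpy as np
import pytest

from calcinet.config import SyntheticCohortConfig
from calcinet.synthetic import generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A 12-patient, 128x128 synthetic cohort shared by cheap tests."""
    out = tmp_path_factory.mktemp("cohort12")
    config = SyntheticCohortConfig(n_patients=12, image_size=128, seed=99)
    manifest = generate_cohort(config, out)
    return config, manifest


@pytest.fixture(scope="session")
def mid_cohort(tmp_path_factory):
    """A 40-patient cohort for split/fold statistics."""
    out = tmp_path_factory.mktemp("cohort40")
    config = SyntheticCohortConfig(n_patients=40, image_size=128, seed=7)
    manifest = generate_cohort(config, out)
    return config, manifest
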