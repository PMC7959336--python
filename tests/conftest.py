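import numpy as np
import pytest

from affectphysio import build_trial_schedule


@pytest.fixture(scope="session")
def study_schedule():
    """The full study layout: 50 facial + 20 mosaic + 20 fixation trials."""
    return build_trial_schedule(50, 20, 20, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
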