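import numpy as np
import pytest

from luscab.records import cohort_to_frame
from luscab.scoring import score_frame
from luscab.simulate import default_paper_config, generate_cohort


@pytest.fixture(scope="session")
def cohort50():
    """The 50-infant synthetic demo cohort (seed 1)."""
    return generate_cohort(default_paper_config(n=50, seed=1))


@pytest.fixture(scope="session")
def cohort5000():
    """A large synthetic cohort for Monte-Carlo calibration checks."""
    return generate_cohort(default_paper_config(n=5000, seed=1))


@pytest.fixture(scope="session")
def scored5000(cohort5000):
    return score_frame(cohort_to_frame(cohort5000))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
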