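import numpy as np
import pytest

from phalanxgmm.procrustes import gpa_align
from phalanxgmm.simulate import generate_population, study_spec


@pytest.fixture
def rng():
    return np.random.default_rng(20230809)


@pytest.fixture(scope="session")
def fore_dataset():
    """Default synthetic forelimb study design (34 specimens, 7 groups)."""
    return generate_population(study_spec("fore", seed=11))


@pytest.fixture(scope="session")
def hind_dataset():
    return generate_population(study_spec("hind", seed=11))


@pytest.fixture(scope="session")
def fore_aligned(fore_dataset):
    return gpa_align(fore_dataset.configurations)


def random_configuration(rng, k=10, scale=1.0):
    return scale * rng.normal(size=(k, 3))
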