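import numpy as np
import pytest

from vascage.synthetic import SyntheticSpec, make_population, make_subject


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec()


@pytest.fixture(scope="session")
def subject_young(default_spec):
    return make_subject(default_spec, 25.0)


@pytest.fixture(scope="session")
def subject_mid(default_spec):
    return make_subject(default_spec, 45.0)


@pytest.fixture(scope="session")
def subject_old(default_spec):
    return make_subject(default_spec, 75.0)


@pytest.fixture(scope="session")
def population_small():
    """40 jittered subjects across the age range (seeded)."""
    return make_population(SyntheticSpec(n_subjects=40, seed=17))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
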