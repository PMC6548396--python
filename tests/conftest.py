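import numpy as np
import pytest

import dyadmed as dm
from dyadmed import reference


@pytest.fixture(scope="session")
def study_paths():
    """The twelve published path estimates used as worked-example inputs."""
    return reference.STUDY_PATHS


@pytest.fixture(scope="session")
def study_config():
    """Generator config at the study regime (n = 312, published paths)."""
    return dm.default_config(n_dyads=312)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240615)


def random_paths(rng, scale=0.5):
    """Random path coefficients for oracle-equivalence checks."""
    vals = rng.uniform(-scale, scale, size=12)
    names = ("a_A1", "a_P1", "a_A2", "a_P2", "b_A1", "b_P1", "b_A2", "b_P2",
             "cp_A1", "cp_P1", "cp_A2", "cp_P2")
    return dm.PathCoefficients(**dict(zip(names, vals)))
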