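import numpy as np
import pytest

from atezopk.config import default_config
from atezopk.pkmodel import IndividualParams
from atezopk.population import PopulationSpec, generate_population


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def small_population():
    """A 50-subject population for fast end-to-end tests."""
    return generate_population(PopulationSpec(n_subjects=50, seed=7))


@pytest.fixture(scope="session")
def typical_params():
    """Reference-subject parameters of the shipped atezolizumab model."""
    return IndividualParams(subject_id=1, cl=0.2, v1=3.28, q=0.546, v2=3.63)


def random_params(rng: np.random.Generator, subject_id: int = 0) -> IndividualParams:
    """A random but physiological mAb-like two-compartment parameter set."""
    return IndividualParams(
        subject_id=subject_id,
        cl=float(np.exp(rng.uniform(np.log(0.05), np.log(1.0)))),
        v1=float(np.exp(rng.uniform(np.log(1.0), np.log(10.0)))),
        q=float(np.exp(rng.uniform(np.log(0.05), np.log(2.0)))),
        v2=float(np.exp(rng.uniform(np.log(1.0), np.log(10.0)))),
    )
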