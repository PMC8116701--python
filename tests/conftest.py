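import numpy as np
import pytest

from iohexolpk import DogCovariates, PopulationModel


@pytest.fixture(scope="session")
def pop() -> PopulationModel:
    """Packaged canine iohexol population model."""
    return PopulationModel()


@pytest.fixture(scope="session")
def healthy_dog() -> DogCovariates:
    return DogCovariates(ckd=0, creatinine=0.98, id="example1")


@pytest.fixture(scope="session")
def ckd_dog() -> DogCovariates:
    return DogCovariates(ckd=1, creatinine=2.25, id="example3")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20230915)
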