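import numpy as np
import pytest

from nirferm.pipeline import (
    StudyConfig,
    default_heterolactic_study,
    default_homolactic_study,
)
from nirferm.simulate import (
    AssayNoiseModel,
    cluster_profile,
    homolactic_profile,
)
from nirferm.spectra import HydrodynamicState, filter19_instrument


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def homolactic():
    return homolactic_profile()


@pytest.fixture
def heterolactic():
    return cluster_profile()


@pytest.fixture(scope="session")
def homo_study():
    return default_homolactic_study(seed=1)


@pytest.fixture(scope="session")
def hetero_study():
    return default_heterolactic_study(seed=1)


@pytest.fixture(scope="session")
def homo_models(homo_study):
    from nirferm.pipeline import build_all_calibrations

    return build_all_calibrations(homo_study)


@pytest.fixture(scope="session")
def hetero_models(hetero_study):
    from nirferm.pipeline import build_all_calibrations

    return build_all_calibrations(hetero_study)


@pytest.fixture(scope="session")
def small_mlr_study():
    """Scaled-down homolactic MLR study for fast pipeline tests."""
    return StudyConfig(
        organism=homolactic_profile(),
        instrument=filter19_instrument(),
        n_calibration=25,
        n_validation=12,
        method="MLR",
        noise=AssayNoiseModel(),
        seed=7,
        hydro=HydrodynamicState(stirring=120.0, airflow=0.0),
    )
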