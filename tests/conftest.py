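import numpy as np
import pytest

from cardiothermal import PopulationConfig, TraitModel, generate_dataset, make_protocol
from cardiothermal.pipeline import extract_metrics


@pytest.fixture(scope="session")
def protocol():
    return make_protocol(9, 25, 2, 1, 19)


@pytest.fixture(scope="session")
def study_config():
    """The full study design: 121/152/134 larvae at 9/12/15 degC, 5 clutches."""
    return PopulationConfig(seed=20240901)


@pytest.fixture(scope="session")
def small_config():
    """A fast miniature cohort for structural and I/O tests."""
    return PopulationConfig(
        n_per_group={9.0: 12, 12.0: 12, 15.0: 12}, n_clutches=3, seed=7
    )


@pytest.fixture(scope="session")
def study_data(study_config):
    return generate_dataset(study_config)


@pytest.fixture(scope="session")
def study_metrics(study_data):
    dataset, _ = study_data
    return extract_metrics(dataset)


@pytest.fixture(scope="session")
def small_data(small_config):
    return generate_dataset(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def deterministic_trait(intercept, slope):
    return TraitModel(intercept, slope, clutch_sd=0.0, individual_sd=0.0)
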