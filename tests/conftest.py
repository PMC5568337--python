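import numpy as np
import pytest

from iopgrs import GeneratorParams, VariantPanel, sample_cohort


@pytest.fixture(scope="session")
def paper_panel() -> VariantPanel:
    return VariantPanel.default()


@pytest.fixture(scope="session")
def default_params() -> GeneratorParams:
    return GeneratorParams.from_profile()


@pytest.fixture(scope="session")
def small_params(default_params) -> GeneratorParams:
    """Calibrated generator with small quotas for fast cohort tests."""
    return default_params.with_updates(**{"quotas": {"control": 40, "ntg": 40, "htg": 40}}
    )


@pytest.fixture(scope="session")
def small_cohort(small_params):
    return sample_cohort(small_params, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20170823)
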