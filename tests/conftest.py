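import numpy as np
import pytest

from radkin import (
    CaseConfig,
    GrowthParams,
    RadiobiologyConstants,
    TreatmentSpec,
    clinical_case_configs,
    rat_case_configs,
)


@pytest.fixture(scope="session")
def rat_configs():
    return rat_case_configs()


@pytest.fixture(scope="session")
def clinical_configs():
    return clinical_case_configs()


@pytest.fixture(scope="session")
def all_configs(rat_configs, clinical_configs):
    return rat_configs + clinical_configs


@pytest.fixture
def simple_config():
    """A small generic irradiated case for unit tests."""
    return CaseConfig(
        label="unit",
        growth=GrowthParams(v0=0.5, td0=5.0, theta=0.8),
        radio=RadiobiologyConstants(alpha=0.2),
        treatment=TreatmentSpec(dose=15.0, t_r=20.0, tau_rad=8.0, t_cl=10.0),
    )


@pytest.fixture
def dense_grid():
    return np.linspace(0.0, 80.0, 1601)
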