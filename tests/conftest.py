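import numpy as np
import pytest

from thalcort.config import ModelConfig
from thalcort.core import PopulationSpec, ReceptorParams
from thalcort.network import build_base_network


@pytest.fixture(scope="session")
def base_net():
    return build_base_network(ModelConfig())


@pytest.fixture()
def exc_pop():
    return PopulationSpec(
        name="Py4", kind="excitatory", V_rest=-65.0, theta_u=-56.0,
        sigma_u=4.0, g_lk=10.0, E_lk=-55.0, kappa=0.25,
    )


@pytest.fixture()
def ampa():
    return ReceptorParams(psi="AMPA", alpha=100.0, beta=50.0, g_max=100.0,
                          E_rev=0.0)


@pytest.fixture()
def gaba():
    return ReceptorParams(psi="GABA_A", alpha=100.0, beta=40.0, g_max=1000.0,
                          E_rev=-85.0)
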