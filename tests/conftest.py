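import numpy as np
import pytest

from pax6rd.params import ModelParameters


@pytest.fixture(scope="session")
def simple_params() -> ModelParameters:
    """A small, well-behaved parameter set for unit tests (not the reference)."""
    return ModelParameters(
        rho_P=2.0, sigma_P=0.3, n_hill=2.0, K_hill=1.0,
        rho_F=1.0, rho_T=1.0,
        delta_P=1.0, delta_F=1.0, delta_T=1.0, delta_C=0.5,
        k_on=5.0, k_off=1.0, k_b=1.0, k_u=1.0, R_tot=1.0,
        beta=2.0, gamma=1.0,
        D_F=0.01, D_T=0.01, D_C=1.0,
    )


@pytest.fixture(scope="session")
def reference_params():
    from pax6rd.params import reference_parameters

    return reference_parameters()


@pytest.fixture(scope="session")
def reference_steady(reference_params):
    from pax6rd.model import homogeneous_steady_state

    return homogeneous_steady_state(reference_params, variant="B")


@pytest.fixture(scope="session")
def reference_dispersion(reference_params, reference_steady):
    from pax6rd.stability import default_k_values, dispersion_relation

    k = default_k_values(domain_length=50.0, dx=0.05)
    return dispersion_relation(reference_params, reference_steady, k, variant="B")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
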