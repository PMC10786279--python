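import numpy as np
import pytest

from digitpattern import stability
from digitpattern.params import reference_parameters


@pytest.fixture(scope="session")
def ref_params():
    return reference_parameters()


@pytest.fixture(scope="session")
def ref_dispersion(ref_params):
    return stability.dispersion_relation(ref_params)


@pytest.fixture(scope="session")
def ref_static(ref_params, ref_dispersion):
    """Reference static-domain pattern, shared by pattern/phase tests."""
    from digitpattern import simulate

    lam = ref_dispersion.lambda_pred
    sigma = ref_dispersion.growth_rates[1:].max()
    return simulate.simulate_static(
        ref_params, L=5 * lam, T=min(40.0 / sigma, 400.0),
        noise_amp=0.01, seed=1, dx=lam / 22,
    )


@pytest.fixture(scope="session")
def ref_growth_config():
    from digitpattern.simulate import GrowthConfig

    from digitpattern.reference import reference_growth_config

    return reference_growth_config()


@pytest.fixture(scope="session")
def ref_growing(ref_params, ref_growth_config):
    """Reference growing-domain run (wildtype), shared across tests."""
    from digitpattern import simulate

    return simulate.simulate_growing(ref_params, ref_growth_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
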