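import numpy as np
import pytest

from carrierflux import ModelParams, Substrate, build_network, solve_steady_state


@pytest.fixture(scope="session")
def default_params():
    """Published calibration, exchange scenario (5 mM labelled cyt / 5 mM unlabelled mat)."""
    return ModelParams()


@pytest.fixture(scope="session")
def default_network(default_params):
    return build_network(default_params)


@pytest.fixture(scope="session")
def default_steady(default_network):
    return solve_steady_state(default_network)


@pytest.fixture(scope="session")
def fast_mixing_params():
    """Weak networks and dilute substrate: the chain mixes within short SSA runs."""
    return ModelParams(dE_M=-200.0, dE_C=-200.0, dE_S=-200.0).with_substrates(
        [Substrate("labelled", 1e-4, 0.0), Substrate("unlabelled", 0.0, 1e-4)]
    )


@pytest.fixture(scope="session")
def fast_mixing_network(fast_mixing_params):
    return build_network(fast_mixing_params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
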