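import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import smtrace as st

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def menu():
    """The built-in six-model candidate menu (single Poisson channel)."""
    return st.builtin_models()


@pytest.fixture(scope="session")
def snr5_trace():
    """One moderate-SNR two-state trace from the reference kinetics k=0.3."""
    params = st.two_state_params(0.3, 0.3, 5.0)
    cfg = st.SimulationConfig(params=params, snr=5.0, c=10_000, n_traces=1, seed=314)
    trace, states = st.simulate_trace(cfg, 0)
    return trace, states, params


@pytest.fixture(scope="session")
def snr5_fit(menu, snr5_trace):
    trace, _, _ = snr5_trace
    return st.fit_hmm(trace, menu["2-state"], seed=0)


@pytest.fixture(scope="session")
def noise_trace():
    """Pure one-state Poisson noise (mean 100, T=10^4)."""
    rng = np.random.default_rng(2024)
    x = rng.poisson(100.0, size=10_000).astype(float)
    return st.Trace("noise", 1.0, x[:, None], {"families": "poisson"})
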