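import numpy as np
import pytest
from hypothesis import settings as hyp_settings

hyp_settings.register_profile("deterministic", derandomize=True, deadline=None)
hyp_settings.load_profile("deterministic")

from dormprey import ParameterSet, integrate, run_preset


@pytest.fixture(scope="session")
def defaults():
    return ParameterSet()


@pytest.fixture(scope="session")
def traj_default_1000(defaults):
    """Full contest at K = 11 over the first 1000 days."""
    return integrate(defaults, t_span=(0.0, 1000.0))


@pytest.fixture(scope="session")
def traj_k13(defaults):
    return integrate(defaults.replace(K=13.0), t_span=(0.0, 1000.0))


@pytest.fixture(scope="session")
def traj_k20(defaults):
    return integrate(defaults.replace(K=20.0), t_span=(0.0, 1000.0))


@pytest.fixture(scope="session")
def traj_k9_3000(defaults):
    """Low-capacity contest, long enough for the stable window."""
    return integrate(defaults.replace(K=9.0), t_span=(0.0, 3000.0))


@pytest.fixture(scope="session")
def traj_default_3000(defaults):
    return integrate(defaults, t_span=(0.0, 3000.0))


@pytest.fixture(scope="session")
def traj_fig1a():
    return run_preset("fig1a")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
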