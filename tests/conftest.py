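import pytest
from hypothesis import HealthCheck, settings

from efneuron.biophysics import Biophysics
from efneuron.morphology import ArtificialNeuronParams, build_artificial_neuron

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def kinetics():
    """Shipped CA1 channel set (loaded once; immutable)."""
    return Biophysics.load()


@pytest.fixture(scope="session")
def passive():
    return Biophysics.passive_only()


@pytest.fixture(scope="session")
def default_params():
    return ArtificialNeuronParams()


@pytest.fixture(scope="session")
def default_tree(default_params):
    return build_artificial_neuron(default_params)
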