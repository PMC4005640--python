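import numpy as np
import pytest

from smfluor import alex, presets, synthetic


@pytest.fixture(scope="session")
def default_instrument():
    return presets.DEFAULT_INSTRUMENT


@pytest.fixture(scope="session")
def free_run(default_instrument):
    """A moderate free-σ54 simulation shared by discrimination/histogram tests."""
    species = presets.preset_species("free-sigma54")
    stream, truth = synthetic.simulate_alex_experiment(
        species, default_instrument, n_bursts=3000, seed=7)
    return stream, truth


@pytest.fixture(scope="session")
def free_table(free_run):
    stream, _ = free_run
    return alex.raw_es(alex.find_bursts(stream))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
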