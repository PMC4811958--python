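import numpy as np
import pytest

from spikeconn.io import SpikeTrain
from spikeconn.simulate import generate_poisson_trains, make_motif_fixture


@pytest.fixture(scope="session")
def motif():
    """Three-neuron common-source fixture: true edges 0->1 and 0->2."""
    return make_motif_fixture(seed=0)


@pytest.fixture(scope="session")
def poisson_pair():
    return generate_poisson_trains(2, 5.0, 30.0, 10000.0, seed=7)


def make_train(spikes, n_samples=10000, fs=1000.0, label="t"):
    return SpikeTrain(
        n_samples=n_samples, spikes=np.asarray(spikes, dtype=np.int64), fs=fs, label=label
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
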