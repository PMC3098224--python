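import numpy as np
import pytest

from hawkesnet import RingProfile, make_random, make_ring


@pytest.fixture(scope="session")
def small_random_net():
    """Weakly coupled inhibition-dominated Bernoulli network (N=120)."""
    return make_random(120, 0.2, 0.1, 0.02, -0.1, seed=7)


@pytest.fixture(scope="session")
def small_regular_net():
    """Fixed per-population out-degree network (N=150; 12 E + 3 I targets each)."""
    return make_random(150, 0.2, 0.1, 0.02, -0.1, fixed_out_degree=True, seed=8)


@pytest.fixture(scope="session")
def small_ring_net():
    """Locally excitatory / globally inhibitory ring (N=120)."""
    return make_ring(
        120, 0.2, RingProfile(12, 0.5), RingProfile(60, 0.1), 0.01, -0.05, seed=9
    )


@pytest.fixture
def two_neuron_net():
    from hawkesnet import Network

    return Network(G=np.array([[0.0, 0.0], [0.5, 0.0]]), types=np.array(["E", "E"]))
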