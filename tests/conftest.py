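import numpy as np
import pytest

from spikeconn.synthetic import (
    NetworkModel,
    SpikeTrainSet,
    generate_delta_motif,
    generate_random_network,
    simulate_izhikevich,
)


@pytest.fixture(scope="session")
def chain_fixture():
    """Zero-jitter 3-neuron chain 0 -> 1 -> 2 with delays 2 and 3 ms."""
    return generate_delta_motif("chain", [2.0, 3.0], event_rate=5.0,
                                jitter_sd=0.0, duration=60.0, seed=11)


@pytest.fixture(scope="session")
def jittered_chain_fixture():
    """Chain with per-edge phase noise: the indirect (0,2) correlation is
    lower and wider than the direct ones."""
    return generate_delta_motif("chain", [2.0, 3.0], event_rate=8.0,
                                jitter_sd=0.5, duration=120.0, seed=12)


@pytest.fixture(scope="session")
def common_input_fixture():
    """Marrying-parents motif: 0 drives 1 (2 ms) and 2 (4 ms)."""
    return generate_delta_motif("common_input", [2.0, 4.0], event_rate=8.0,
                                jitter_sd=0.5, duration=120.0, seed=13)


@pytest.fixture(scope="session")
def random_trains():
    """Small random Poisson-ish spike set for oracle comparisons."""
    rng = np.random.default_rng(7)
    trains = [np.unique(rng.uniform(0, 10.0, rng.integers(50, 150)))
              for _ in range(4)]
    return SpikeTrainSet(4, trains, 10.0)


@pytest.fixture(scope="session")
def small_izhikevich():
    """One simulated 10-neuron benchmark network (short recording)."""
    model = generate_random_network(10, 2.0, seed=42)
    trains = simulate_izhikevich(model, 120.0, seed=43)
    return model, trains
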