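import numpy as np
import pytest

import momentropy as mt


@pytest.fixture(scope="session")
def small_connectome():
    """8-node synthetic connectome for cheap end-to-end runs."""
    return mt.generate_synthetic_connectome(n_nodes=8, density=0.6, seed=42)


@pytest.fixture(scope="session")
def pair_connectome():
    """Two mutually coupled nodes 10 mm apart."""
    w = np.array([[0.0, 1.0], [1.0, 0.0]])
    d = np.array([[0.0, 10.0], [10.0, 0.0]])
    return mt.Connectome(weights=w, distances=d)


@pytest.fixture(scope="session")
def triangle_connectome():
    """Fully connected 3-node connectome with weights {1, 2, 3}."""
    w = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
    d = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
    return mt.Connectome(weights=w, distances=d)


def tone(freq, fs=500.0, duration=10.0, amplitude=1.0, phase=0.0, n_nodes=1):
    """SignalSet holding identical sinusoids on every node."""
    t = np.arange(int(round(duration * fs))) / fs
    x = amplitude * np.sin(2 * np.pi * freq * t + phase)
    return mt.SignalSet(values=np.tile(x, (n_nodes, 1)), sampling_rate=fs)


@pytest.fixture
def make_tone():
    return tone
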