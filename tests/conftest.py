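import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_network(rng, n_nodes=12, p=0.3, weighted=False, level="protein"):
    """A random undirected network for round-trip and invariant tests."""
    from netrewire.model import Network

    if level == "protein":
        names = [f"P{i:03d}" for i in range(n_nodes)]
    else:
        names = [f"P{i:03d}|PF{i % 5:03d}|{i % 2}" for i in range(n_nodes)]
    net = Network(level=level)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p:
                w = float(np.round(rng.random(), 6)) if weighted and rng.random() < 0.5 else None
                net.add_edge(names[i], names[j], w)
    return net
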