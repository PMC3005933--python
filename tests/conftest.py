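import sys
from pathlib import Path

import networkx as nx
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from adhocnet.synthetic import default_spec, figure2_style_fixture, planted_module_graph


def random_graph(seed: int, n_max: int = 12, p: float = 0.4) -> nx.Graph:
    """Seeded Erdos-Renyi graph with 4..n_max nodes."""
    import numpy as np

    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, n_max + 1))
    return nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))


@pytest.fixture
def demo_graph() -> nx.Graph:
    return figure2_style_fixture()


@pytest.fixture
def planted():
    spec = default_spec(seed=11)
    return planted_module_graph(spec)
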