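import pytest

from netctrl import synthgen
from netctrl.graph_core import DirectedNetwork


@pytest.fixture
def diamond() -> DirectedNetwork:
    return synthgen.fixture("diamond")


@pytest.fixture
def path3() -> DirectedNetwork:
    return synthgen.fixture("path3")


@pytest.fixture
def star3() -> DirectedNetwork:
    return synthgen.fixture("star3")


@pytest.fixture
def demo10() -> DirectedNetwork:
    """Ten-node example with two driver nodes and non-trivial substitutes."""
    return synthgen.fixture("substitution_demo")


def small_sweep(count: int, n_max: int = 8, seed: int = 1):
    """Shared seeded sweep of small ER digraphs for oracle comparisons."""
    return synthgen.sweep_small_digraphs(count, n_max, (0.05, 0.9), seed=seed)
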