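import numpy as np
import pytest

from ppinalign import BitScoreTable, Network, normalize_bit_scores


@pytest.fixture
def path_graph():
    """a - b - c."""
    return Network([("a", "b"), ("b", "c")], name="path3")


@pytest.fixture
def triangle():
    return Network([("x", "y"), ("y", "z"), ("x", "z")], name="tri")


def make_self_bits(net: Network, value: float = 100.0) -> BitScoreTable:
    """Within-network table with self-scores at the maximum."""
    t = BitScoreTable()
    for u in net.nodes:
        t.set(u, u, value)
    return normalize_bit_scores(t)


def identity_cross_bits(net: Network, value: float = 100.0) -> BitScoreTable:
    """Cross table concentrated on the identity (for self-alignment)."""
    t = BitScoreTable()
    for u in net.nodes:
        t.set(u, u, value)
    return normalize_bit_scores(t)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
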