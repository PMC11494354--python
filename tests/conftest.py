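import math

import numpy as np
import pytest

from liquidnet.params import DomainBoundary
from liquidnet.network import LiquidNetwork, init_honeycomb

HEX_AREA = 1.5 * math.sqrt(3.0)  # area of a unit-edge regular hexagon


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def honeycomb_r15():
    """Unit-edge honeycomb clipped to the 15 µm circle (the reference start)."""
    return init_honeycomb(1.0, DomainBoundary("circle", radius=15.0))


@pytest.fixture
def single_hexagon():
    """One free-standing hexagon ring (degree-2 ring, no enclosure)."""
    net = LiquidNetwork(DomainBoundary("none"))
    ang = np.arange(6) * (math.pi / 3.0)
    ids = [net.add_node((math.cos(a), math.sin(a))) for a in ang]
    for idx in range(6):
        net.add_edge(ids[idx], ids[(idx + 1) % 6])
    return net


def make_two_gon(sep: float = 1.0, ext: float = 2.0) -> LiquidNetwork:
    """Doubly-connected pair with one external neighbor each."""
    net = LiquidNetwork(DomainBoundary("none"))
    n1 = net.add_node((-ext, 0.0), boundary=True)
    i = net.add_node((-sep / 2, 0.0))
    j = net.add_node((sep / 2, 0.0))
    n2 = net.add_node((ext, 0.0), boundary=True)
    net.add_edge(n1, i)
    net.add_edge(i, j)
    net.add_edge(i, j)
    net.add_edge(j, n2)
    return net
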