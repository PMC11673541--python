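"""Shared fixtures: small analytic networks and a seeded random network."""

from __future__ import annotations

import numpy as np
import pytest

from angiomesh.network import VascularNetwork


@pytest.fixture
def series_chain():
    """Three equal segments in series from an artery node to a vein node.

    Analytic solution: equal flow through every segment, pressures divide
    linearly along the chain.
    """
    net = VascularNetwork()
    n0 = net.add_node(0.0, 0.0, kind="parent", bc="artery")
    n1 = net.add_node(1.0, 0.0, kind="parent")
    n2 = net.add_node(2.0, 0.0, kind="parent")
    n3 = net.add_node(3.0, 0.0, kind="parent", bc="vein")
    for a, b in ((n0, n1), (n1, n2), (n2, n3)):
        net.add_segment(a, b, diameter=0.1, order=1, parent=True)
    return net


@pytest.fixture
def y_junction():
    """Degree-3 junction: straight order-1 continuation plus an order-2
    daughter leaving at exactly 86 degrees (constructed, no recorded events).
    """
    net = VascularNetwork()
    a = net.add_node(0.0, 0.0, kind="parent", bc="artery")
    j = net.add_node(1.0, 0.0, kind="junction")
    c = net.add_node(2.0, 0.0, kind="parent", bc="vein")
    th = np.radians(86.0)
    d = net.add_node(1.0 + np.cos(th), np.sin(th), kind="sprout")
    net.add_segment(a, j, diameter=0.1, order=1, generation=0)
    net.add_segment(j, c, diameter=0.1, order=1, generation=1)
    net.add_segment(j, d, diameter=0.05, order=2, generation=1)
    return net


def make_toy_loop(d0: float = 0.05) -> VascularNetwork:
    """Frozen parent chain artery->vein with a 4-segment free loop.

    The loop leaves the parent at one interior node and rejoins at the
    next, so the parent feed resistance loads the loop: its adaptation has
    a stable interior equilibrium (diameters strictly inside the clamps).
    """
    net = VascularNetwork()
    p0 = net.add_node(0.0, 0.0, kind="parent", bc="artery")
    p1 = net.add_node(1.0, 0.0, kind="parent")
    p2 = net.add_node(2.0, 0.0, kind="parent")
    p3 = net.add_node(3.0, 0.0, kind="parent", bc="vein")
    for a, b in ((p0, p1), (p1, p2), (p2, p3)):
        net.add_segment(a, b, diameter=0.18, order=1, parent=True)
    q1 = net.add_node(0.75, -0.6)
    q2 = net.add_node(1.5, -0.9)
    q3 = net.add_node(2.25, -0.6)
    for a, b in ((p1, q1), (q1, q2), (q2, q3), (q3, p2)):
        net.add_segment(a, b, diameter=d0, order=2)
    return net


@pytest.fixture
def toy_loop():
    return make_toy_loop()


def make_random_network(n_segments: int = 50, seed: int = 12345) -> VascularNetwork:
    """Seeded random connected network with ``n_segments`` segments.

    A random tree over scattered nodes guarantees connectivity; extra
    chords close loops.  One node is tagged artery and one vein.
    """
    rng = np.random.default_rng(seed)
    n_nodes = n_segments - 10
    net = VascularNetwork()
    pts = rng.uniform(0.0, 5.0, size=(n_nodes, 2))
    for x, y in pts:
        net.add_node(float(x), float(y))
    edges = set()
    for i in range(1, n_nodes):  # random tree: attach each node to an earlier one
        j = int(rng.integers(0, i))
        edges.add((j, i))
        net.add_segment(j, i, diameter=float(rng.uniform(0.02, 0.12)), order=2)
    while net.n_segments < n_segments:  # chords
        a, b = (int(v) for v in rng.integers(0, n_nodes, size=2))
        if a == b or (min(a, b), max(a, b)) in edges:
            continue
        edges.add((min(a, b), max(a, b)))
        net.add_segment(a, b, diameter=float(rng.uniform(0.02, 0.12)), order=2)
    net.g.nodes[0]["bc"] = "artery"
    net.g.nodes[n_nodes - 1]["bc"] = "vein"
    return net


@pytest.fixture
def random_network():
    return make_random_network()
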