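"""Shared fixtures: tiny hand-built networks and independent oracles."""

import numpy as np
import pandas as pd
import pytest

from streamtn.network import StreamNetwork


@pytest.fixture
def single_edge_network():
    """One 10-km straight edge; node 1 upstream at (10, 0), outlet 0 at origin."""
    return StreamNetwork(nodes={0: (0.0, 0.0), 1: (10.0, 0.0)}, edges=[(1, 0, 10.0)], outlet=0)


@pytest.fixture
def long_edge_network():
    """One 25-km straight edge for arc-length spacing tests."""
    return StreamNetwork(nodes={0: (0.0, 0.0), 1: (25.0, 0.0)}, edges=[(1, 0, 25.0)], outlet=0)


@pytest.fixture
def y_network():
    """Y-shaped network: outlet 0, junction 1 at 10 km, two 10-km branches."""
    nodes = {0: (0.0, 0.0), 1: (0.0, 10.0), 2: (-6.0, 18.0), 3: (6.0, 18.0)}
    edges = [(1, 0, 10.0), (2, 1, 10.0), (3, 1, 10.0)]
    return StreamNetwork(nodes=nodes, edges=edges, outlet=0)


def make_sites(rows):
    """Site table from (site_id, edge_u, edge_v, offset_km) tuples; planar
    coordinates interpolated are not needed for river-distance work."""
    ids, eu, ev, off = zip(*rows)
    return pd.DataFrame({"site_id": ids, "edge_u": eu, "edge_v": ev, "offset_km": off})


def random_tree_network(rng, n_edges):
    """Random tree with arbitrary topology, positive lengths and coordinates.

    Built by attaching each new node to a uniformly chosen existing node —
    independent of the package's bifurcation generator.
    """
    nodes = {0: (0.0, 0.0)}
    edges = []
    for new in range(1, n_edges + 1):
        parent = int(rng.integers(0, new))
        nodes[new] = (float(rng.uniform(-50, 50)), float(rng.uniform(-50, 50)))
        chord = float(np.hypot(
            nodes[new][0] - nodes[parent][0], nodes[new][1] - nodes[parent][1]
        ))
        # channel length is the chord stretched by a sinuosity factor >= 1,
        # keeping the network geometrically consistent
        edges.append((new, parent, max(chord, 0.1) * float(rng.uniform(1.0, 1.6))))
    return StreamNetwork(nodes=nodes, edges=edges, outlet=0)


def random_sites_on(network, rng, n_sites):
    rows = []
    edges = network.edges
    for i in range(n_sites):
        u, v, length = edges[int(rng.integers(0, len(edges)))]
        rows.append((f"T{i:02d}", u, v, float(rng.uniform(0.0, length))))
    return make_sites(rows)


def oracle_river_distances(sites, network):
    """Independent all-pairs along-network distances via networkx Dijkstra on
    a subdivided graph: every site becomes a graph node splitting its edge."""
    import networkx as nx

    g = nx.Graph()
    on_edge = {}
    for idx, row in sites.iterrows():
        on_edge.setdefault((row["edge_u"], row["edge_v"]), []).append(
            (float(row["offset_km"]), f"site:{row['site_id']}")
        )
    for u, v, length in network.edges:
        pts = sorted(on_edge.get((u, v), []))
        prev, prev_off = u, 0.0
        for off, name in pts:
            g.add_edge(prev, name, weight=off - prev_off)
            prev, prev_off = name, off
        g.add_edge(prev, v, weight=length - prev_off)
    n = len(sites)
    out = np.zeros((n, n))
    ids = [f"site:{s}" for s in sites["site_id"]]
    for i, a in enumerate(ids):
        lengths = nx.single_source_dijkstra_path_length(g, a)
        for j, b in enumerate(ids):
            out[i, j] = lengths[b]
    return out
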