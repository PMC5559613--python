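"""Stream-network container: a geometric tree rooted at the watershed outlet.

The network is stored as an edge list ``(upstream node, downstream node,
length km)`` together with planar node coordinates in km (projected; no
geographic coordinates).  Validation enforces the tree invariants every other
module relies on: connectivity, acyclicity, a single outlet with no downstream
edge, and exactly one downstream edge per non-outlet node.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

import networkx as nx
import numpy as np

from .exceptions import NetworkError

NodeId = int
Coord = Tuple[float, float]
Edge = Tuple[NodeId, NodeId, float]


@dataclass(frozen=True)
class StreamNetwork:
    """A dendritic stream network rooted at ``outlet``.

    Parameters
    ----------
    nodes
        Mapping node id -> ``(x, y)`` planar coordinates in km.
    edges
        List of ``(upstream, downstream, length_km)`` tuples.  Edges are
        oriented in the flow direction; every path of downstream edges ends at
        the outlet.
    outlet
        Node id of the watershed outlet (the tree root).
    """

    nodes: Dict[NodeId, Coord]
    edges: List[Edge]
    outlet: NodeId

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------ checks
    def validate(self) -> None:
        if self.outlet not in self.nodes:
            raise NetworkError(f"outlet node {self.outlet!r} not among nodes")
        for nid, (x, y) in self.nodes.items():
            if not (math.isfinite(x) and math.isfinite(y)):
                raise NetworkError(f"node {nid!r} has non-finite coordinates {(x, y)}")
        downstream: Dict[NodeId, NodeId] = {}
        for u, v, length in self.edges:
            if u not in self.nodes or v not in self.nodes:
                raise NetworkError(f"edge ({u!r}, {v!r}) references unknown node")
            if not (length > 0 and math.isfinite(length)):
                raise NetworkError(f"edge ({u!r}, {v!r}) has non-positive length {length}")
            if u in downstream:
                raise NetworkError(f"node {u!r} has more than one downstream edge")
            downstream[u] = v
        if self.outlet in downstream:
            raise NetworkError("outlet must have no downstream edge")
        g = self.graph()
        if g.number_of_nodes() != len(self.nodes):
            raise NetworkError("isolated nodes present")
        if not nx.is_connected(g):
            raise NetworkError("network is disconnected")
        if g.number_of_edges() != len(self.nodes) - 1:
            cycle = nx.find_cycle(g)
            raise NetworkError(f"network contains a cycle through nodes {sorted({n for e in cycle for n in e[:2]})}")

    # ------------------------------------------------------------- conversions
    def graph(self) -> nx.Graph:
        """Undirected weighted graph view (weight attribute ``length``)."""
        g = nx.Graph()
        for nid, xy in self.nodes.items():
            g.add_node(nid, x=xy[0], y=xy[1])
        for u, v, length in self.edges:
            g.add_edge(u, v, length=length)
        return g

    # -------------------------------------------------------------- properties
    @property
    def total_length(self) -> float:
        """Total channel length in km."""
        return float(sum(length for _, _, length in self.edges))

    def source_nodes(self) -> List[NodeId]:
        """Headwater (leaf) nodes: upstream ends with no further upstream edge."""
        ups = {u for u, _, _ in self.edges}
        downs = {v for _, v, _ in self.edges}
        return sorted(ups - downs)

    def downstream_map(self) -> Dict[NodeId, Tuple[NodeId, float]]:
        """Per node (except outlet): the downstream node and edge length."""
        return {u: (v, length) for u, v, length in self.edges}

    def edge_lengths(self) -> Dict[Tuple[NodeId, NodeId], float]:
        return {(u, v): length for u, v, length in self.edges}

    def distances_to_outlet(self) -> Dict[NodeId, float]:
        """Along-network distance from every node to the outlet (km)."""
        down = self.downstream_map()
        dist: Dict[NodeId, float] = {self.outlet: 0.0}

        def resolve(n: NodeId) -> float:
            chain = []
            while n not in dist:
                chain.append(n)
                n = down[n][0]
            d = dist[n]
            for m in reversed(chain):
                d = dist[down[m][0]] + down[m][1]
                dist[m] = d
            return dist[chain[0]] if chain else d

        for nid in self.nodes:
            resolve(nid)
        return dist

    def interpolate(self, edge_u: NodeId, edge_v: NodeId, offset_km: float) -> Coord:
        """Planar coordinates of a point ``offset_km`` below the upstream node
        of edge ``(edge_u, edge_v)``, by linear interpolation along the edge."""
        length = self.edge_lengths().get((edge_u, edge_v))
        if length is None:
            raise NetworkError(f"no edge ({edge_u!r}, {edge_v!r}) in network")
        if not 0.0 <= offset_km <= length + 1e-9:
            raise NetworkError(
                f"offset {offset_km} outside edge ({edge_u!r}, {edge_v!r}) of length {length}"
            )
        t = min(max(offset_km / length, 0.0), 1.0)
        (x0, y0), (x1, y1) = self.nodes[edge_u], self.nodes[edge_v]
        return (x0 + t * (x1 - x0), y0 + t * (y1 - y0))
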