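"""Between-site distance matrices: straight-line and river (along-network).

Both metrics feed the exponential correlation model and neighbor selection.
River distance is the symmetric shortest-path distance through the stream
network, with partial-edge offsets honoured at both ends; it carries no
flow-direction asymmetry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial.distance import pdist, squareform

from .exceptions import NetworkError, ValidationError
from .network import StreamNetwork

STRAIGHT_LINE = "straight-line"
RIVER = "river"

#: columns a site table must carry to be snapped onto the network
POSITION_COLUMNS = ("site_id", "x", "y", "edge_u", "edge_v", "offset_km")


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise distances (km) with its site ordering."""

    site_ids: List
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.site_ids), len(self.site_ids)):
            raise ValidationError("distance matrix shape does not match site ids")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise ValidationError("distances must be non-negative")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids, columns=self.site_ids)

    def submatrix(self, ids: Sequence) -> "DistanceMatrix":
        idx = [self.site_ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)], self.metric)


def euclidean_distance_matrix(sites: pd.DataFrame) -> DistanceMatrix:
    """Pairwise straight-line distances from projected planar coordinates."""
    for col in ("x", "y"):
        if col not in sites.columns:
            raise ValidationError(f"site table lacks coordinate column {col!r}")
        bad = sites.loc[sites[col].isna(), "site_id"]
        if len(bad):
            raise ValidationError(f"missing {col} coordinate for site(s) {list(bad)}")
    xy = sites[["x", "y"]].to_numpy(float)
    d = squareform(pdist(xy)) if len(xy) > 1 else np.zeros((len(xy), len(xy)))
    return DistanceMatrix(list(sites["site_id"]), d, STRAIGHT_LINE)


def _node_distance_matrix(network: StreamNetwork):
    """All-pairs shortest-path distances between network nodes."""
    node_ids = sorted(network.nodes)
    idx = {n: i for i, n in enumerate(node_ids)}
    rows, cols, data = [], [], []
    for u, v, length in network.edges:
        rows += [idx[u], idx[v]]
        cols += [idx[v], idx[u]]
        data += [length, length]
    n = len(node_ids)
    adj = csr_matrix((data, (rows, cols)), shape=(n, n))
    return idx, dijkstra(adj, directed=False)


def _check_positions(sites: pd.DataFrame, network: StreamNetwork) -> None:
    lengths = network.edge_lengths()
    for _, row in sites.iterrows():
        key = (row["edge_u"], row["edge_v"])
        if key not in lengths:
            raise NetworkError(f"site {row['site_id']!r} references unknown edge {key}")
        if not 0.0 <= row["offset_km"] <= lengths[key] + 1e-9:
            raise NetworkError(
                f"site {row['site_id']!r} offset {row['offset_km']} outside edge "
                f"{key} of length {lengths[key]}"
            )


def river_cross_distances(
    sites_a: pd.DataFrame, sites_b: pd.DataFrame, network: StreamNetwork
) -> np.ndarray:
    """Along-network distances between every site in ``sites_a`` and ``sites_b``.

    Each site is located by ``(edge_u, edge_v, offset_km)`` with the offset
    measured downstream from the upstream node.  In a tree the shortest path
    from an on-edge point must leave through one of its edge endpoints, so the
    pairwise distance is the minimum over the four endpoint combinations, with
    a direct arc-length term for pairs sharing an edge.
    """
    _check_positions(sites_a, network)
    _check_positions(sites_b, network)
    idx, nd = _node_distance_matrix(network)
    lengths = network.edge_lengths()

    def arrays(sites):
        iu = sites["edge_u"].map(idx).to_numpy(int)
        iv = sites["edge_v"].map(idx).to_numpy(int)
        off = sites["offset_km"].to_numpy(float)
        ln = np.array([lengths[(u, v)] for u, v in zip(sites["edge_u"], sites["edge_v"])])
        return iu, iv, off, ln

    au, av, ao, al = arrays(sites_a)
    bu, bv, bo, bl = arrays(sites_b)

    # distance from each site to its own edge endpoints
    a_to_u, a_to_v = ao, al - ao
    b_to_u, b_to_v = bo, bl - bo

    d = np.minimum.reduce(
        [
            a_to_u[:, None] + nd[np.ix_(au, bu)] + b_to_u[None, :],
            a_to_u[:, None] + nd[np.ix_(au, bv)] + b_to_v[None, :],
            a_to_v[:, None] + nd[np.ix_(av, bu)] + b_to_u[None, :],
            a_to_v[:, None] + nd[np.ix_(av, bv)] + b_to_v[None, :],
        ]
    )
    same_edge = (au[:, None] == bu[None, :]) & (av[:, None] == bv[None, :])
    direct = np.abs(ao[:, None] - bo[None, :])
    return np.where(same_edge, np.minimum(d, direct), d)


def river_distance_matrix(sites: pd.DataFrame, network: StreamNetwork) -> DistanceMatrix:
    """Symmetric along-network shortest-path distances between all site pairs."""
    d = river_cross_distances(sites, sites, network)
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)  # enforce exact symmetry against float noise
    return DistanceMatrix(list(sites["site_id"]), d, RIVER)


def snap_sites_to_network(sites: pd.DataFrame, network: StreamNetwork, warn_km: float = 1.0) -> pd.DataFrame:
    """Snap sites given only by planar coordinates to the nearest edge point.

    Adds/overwrites ``edge_u``, ``edge_v``, ``offset_km`` and records the snap
    displacement in ``snap_km``.  Snaps farther than ``warn_km`` warn.
    """
    out = sites.copy()
    eu, ev, off, snap = [], [], [], []
    for _, row in sites.iterrows():
        p = np.array([row["x"], row["y"]])
        best = None
        for u, v, length in network.edges:
            a = np.array(network.nodes[u])
            b = np.array(network.nodes[v])
            seg = b - a
            t = float(np.clip(np.dot(p - a, seg) / np.dot(seg, seg), 0.0, 1.0))
            q = a + t * seg
            dist = float(np.hypot(*(p - q)))
            if best is None or dist < best[0]:
                best = (dist, u, v, t * length)
        d0, u, v, o = best
        if d0 > warn_km:
            warnings.warn(
                f"site {row['site_id']!r} snapped {d0:.2f} km to edge ({u}, {v})"
            )
        eu.append(u); ev.append(v); off.append(o); snap.append(d0)
    out["edge_u"], out["edge_v"], out["offset_km"], out["snap_km"] = eu, ev, off, snap
    return out


def nearest_neighbors(target_id, candidate_ids: Sequence, D: DistanceMatrix, m: int) -> List:
    """The ``m`` candidates nearest to ``target_id``, ascending by distance.

    Ties are broken by ascending site id so the selection is deterministic
    across platforms.  The target itself is excluded if present among the
    candidates.
    """
    cands = [c for c in candidate_ids if c != target_id]
    if m > len(cands):
        raise ValidationError(f"m={m} exceeds the {len(cands)} available candidates")
    ti = D.site_ids.index(target_id)
    order = sorted(cands, key=lambda c: (D.values[ti, D.site_ids.index(c)], c))
    return order[:m]
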