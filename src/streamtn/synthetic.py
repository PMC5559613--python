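"""Synthetic watershed generator.

Emulates the statistical structure the spatial-regression model assumes so the
whole pipeline can be exercised without field data: a dendritic stream network
over a ~7,335 km^2 region, ~41 monitoring sites along main stem and
tributaries, sub-watershed covariates in four categories (topography, LULC
composition, hydrologic-soil-group composition, pollution sources), and
log-normally distributed TN whose LnTN residuals carry exponential spatial
correlation with a small nugget and a long range.

Default operating point: n_sites=41, theta1=0.08, theta2=250 km, river
distance, with regression coefficients matching the river-distance fit of the
study design (intercept -3.118; cropland +0.019; soil group C -0.023;
ln point-source load +0.262; ln rural population density +0.454) and residual
variance sigma^2 = 0.35 on the LnTN scale.

Reproducibility: one global integer seed fans out to fixed per-stage
sub-seeds (network, sites, covariates, TN) via ``numpy.random.SeedSequence``
spawn keys, so each stage is individually reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import covariates as cov
from .covariates import DEFAULT_VARIABLES, PointSource, area_weighted_density, assemble_design_matrix
from .distances import RIVER, STRAIGHT_LINE, euclidean_distance_matrix, river_distance_matrix
from .exceptions import ConfigError, SimulationError, ValidationError
from .model import correlation_matrix
from .network import StreamNetwork

_STAGES = {"network": 0, "sites": 1, "covariates": 2, "sources": 3, "tn": 4}

#: region side lengths (km) giving the ~7,335 km^2 study-area footprint; the
#: basin is elongated along its ~220 km main stem rather than square
DEFAULT_EXTENT = (146.0, 50.2)

#: river-distance coefficient set of the study design (LnTN scale)
DEFAULT_BETA: Dict[str, float] = {
    "intercept": -3.118,
    "cropland_pct": 0.019,
    "soil_c_pct": -0.023,
    "point_load": 0.262,
    "rural_pop_density": 0.454,
}

#: per-covariate distribution parameters; compositional families are drawn
#: from Dirichlet distributions scaled to 100 so closure is exact, with
#: concentrations tuned to the quoted spreads (cropland SD ~22%, soil-C SD
#: ~28%); densities and loads are log-normal.
DEFAULT_COVARIATE_SPEC: Dict[str, dict] = {
    "lulc": {
        "means": {
            "cropland_pct": 0.631, "rural_dev_pct": 0.182, "forestland_pct": 0.078,
            "grassland_pct": 0.043, "urban_dev_pct": 0.020, "wetland_pct": 0.010,
            "shrub_pct": 0.010, "barren_pct": 0.010, "road_pct": 0.008,
            "water_pct": 0.008,
        },
        "concentration": 3.6,
    },
    "soil": {
        "means": {"soil_a_pct": 0.25, "soil_b_pct": 0.27, "soil_c_pct": 0.28, "soil_d_pct": 0.20},
        "concentration": 1.7,
    },
    "mean_slope": {"meanlog": 0.8, "sdlog": 0.6},          # degrees
    "area_km2": {"meanlog": 4.5, "sdlog": 0.8},
    "rural_pop_density": {"meanlog": 5.0, "sdlog": 0.5, "n_counties": 10},  # persons/km^2
    "manure_density": {"meanlog": 8.5, "sdlog": 0.6},      # kg/(km^2 yr)
    # composite sub-watershed sources; placement is upstream-weighted
    # (weight ~ edge length x distance-to-outlet^upstream_weight)
    "point_sources": {
        "n_sources": 80, "load_meanlog": 5.5, "load_sdlog": 0.5, "upstream_weight": 1.5,
    },  # kg/yr
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic-watershed realization."""

    seed: int = 0
    n_sites: int = 41
    beta: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    sigma2: float = 0.35
    theta1: float = 0.08
    theta2: float = 250.0
    metric: str = RIVER
    variables: Tuple[str, ...] = DEFAULT_VARIABLES
    covariate_spec: Mapping[str, dict] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATE_SPEC.items()}
    )
    n_branch_events: int = 60
    region_extent: Tuple[float, float] = DEFAULT_EXTENT

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta1 <= 1.0:
            raise ConfigError(f"theta1={self.theta1} outside [0, 1]")
        if self.theta2 <= 0:
            raise ConfigError(f"theta2={self.theta2} must be positive")
        if self.sigma2 < 0:
            raise ConfigError("sigma2 must be non-negative")
        if self.metric not in (RIVER, STRAIGHT_LINE):
            raise ConfigError(f"unknown metric {self.metric!r}")
        if len(self.beta) != 1 + len(self.variables):
            raise ConfigError(
                f"beta has {len(self.beta)} entries; expected intercept + "
                f"{len(self.variables)} covariates"
            )


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STAGES[stage],)))


# --------------------------------------------------------------------------
# network
# --------------------------------------------------------------------------

def generate_network(
    seed: int,
    n_branch_events: int = 60,
    region_extent: Tuple[float, float] = DEFAULT_EXTENT,
) -> StreamNetwork:
    """Random dendritic network by recursive bifurcation from the outlet.

    A main stem grows upstream from the outlet along the basin's long axis;
    each branch event attaches a new tributary chain at a randomly chosen
    interior node, adding exactly one headwater leaf.  Branch lengths
    attenuate with level and branch angles are random, mimicking a natural
    dendritic topology.  Coordinates are rescaled to fit ``region_extent``
    and each edge's channel length is its planar chord times a sinuosity
    factor >= 1, so river distance always dominates straight-line distance.
    """
    ex, ey = region_extent
    if ex <= 0 or ey <= 0:
        raise ValidationError(f"region extent must be positive, got {region_extent}")
    if n_branch_events < 0:
        raise ValidationError("n_branch_events must be non-negative")
    rng = _stage_rng(seed, "network")

    nodes: Dict[int, Tuple[float, float]] = {0: (0.0, 0.0)}
    edges: List[Tuple[int, int, float]] = []  # (upstream, downstream, length)
    level: Dict[int, int] = {0: 0}
    heading: Dict[int, float] = {}
    next_id = 1

    def grow_chain(
        start: int, n_seg: int, seg_len: float, base_angle: float, jitter: float
    ) -> None:
        nonlocal next_id
        node = start
        angle = base_angle
        for _ in range(n_seg):
            # meander around the chain's own heading so each tributary stays
            # directed while the basin keeps its elongated shape
            angle = base_angle + 0.75 * (angle - base_angle) + rng.normal(0.0, jitter)
            length = seg_len * rng.uniform(0.7, 1.3)
            x, y = nodes[node]
            new = next_id
            next_id += 1
            nodes[new] = (x + length * math.cos(angle), y + length * math.sin(angle))
            edges.append((new, node, length))  # oriented upstream -> downstream
            level[new] = level[node] if node != start else level[start]
            heading[new] = angle
            node = new

    # main stem: a directed, mildly sinuous channel along the basin's long axis
    grow_chain(0, n_seg=26, seg_len=9.0, base_angle=0.0, jitter=0.3)

    for _ in range(n_branch_events):
        ups = {u for u, _, _ in edges}
        downs = {v for _, v, _ in edges}
        interior = sorted((ups & downs))  # has both an upstream and a downstream edge
        attach = int(rng.choice(interior))
        side = rng.choice([-1.0, 1.0])
        base = heading.get(attach, math.pi / 4) + side * rng.uniform(0.5, 1.3)
        depth = level[attach] + 1
        seg_len = 9.0 * (0.9**depth) * rng.uniform(0.8, 1.2)
        n_seg = int(rng.integers(3, 9))
        lvl_backup = level[attach]
        level[attach] = depth  # children of the new chain inherit this depth
        grow_chain(attach, n_seg=n_seg, seg_len=max(seg_len, 1.0), base_angle=base, jitter=0.55)
        level[attach] = lvl_backup

    # rescale into the region with a small margin; x and y scale independently
    # so the basin fills its elongated extent
    xs = np.array([p[0] for p in nodes.values()])
    ys = np.array([p[1] for p in nodes.values()])
    scale_x = 0.92 * ex / max(xs.max() - xs.min(), 1e-9)
    scale_y = 0.92 * ey / max(ys.max() - ys.min(), 1e-9)
    x0, y0 = xs.min(), ys.min()
    scaled = {
        nid: (0.04 * ex + scale_x * (x - x0), 0.04 * ey + scale_y * (y - y0))
        for nid, (x, y) in nodes.items()
    }
    # channel length exceeds the straight chord between edge endpoints by a
    # per-edge sinuosity factor, as in a digitized river network
    sinuosity = np.exp(rng.normal(0.38, 0.12, size=len(edges)))
    scaled_edges = [
        (u, v, max(s, 1.0) * math.dist(scaled[u], scaled[v]))
        for (u, v, _), s in zip(edges, sinuosity)
    ]
    return StreamNetwork(nodes=scaled, edges=scaled_edges, outlet=0)


# --------------------------------------------------------------------------
# sites and covariates
# --------------------------------------------------------------------------

def generate_sites(
    network: StreamNetwork, n_sites: int, seed: int, density_cap_per_km: float = 1.0
) -> pd.DataFrame:
    """Monitoring sites placed uniformly at random along total channel length.

    Each site carries its network position ``(edge_u, edge_v, offset_km)``
    (offset measured from the upstream node) and interpolated planar
    coordinates.  Exceeding the configured site density warns but proceeds.
    """
    if n_sites < 1:
        raise ValidationError("n_sites must be at least 1")
    if n_sites > density_cap_per_km * network.total_length:
        warnings.warn(
            f"{n_sites} sites exceed the density cap of {density_cap_per_km}/km "
            f"on {network.total_length:.0f} km of channel"
        )
    rng = _stage_rng(seed, "sites")
    lengths = np.array([e[2] for e in network.edges])
    picks = rng.choice(len(network.edges), size=n_sites, p=lengths / lengths.sum())
    offsets = rng.uniform(0.0, lengths[picks])
    rows = []
    for i, (k, off) in enumerate(zip(picks, offsets)):
        u, v, length = network.edges[k]
        x, y = network.interpolate(u, v, off)
        rows.append((f"S{i + 1:03d}", x, y, u, v, float(off)))
    return pd.DataFrame(rows, columns=["site_id", "x", "y", "edge_u", "edge_v", "offset_km"])


def generate_point_sources(
    network: StreamNetwork,
    seed: int,
    n_sources: int = 80,
    load_meanlog: float = 5.5,
    load_sdlog: float = 0.5,
    upstream_weight: float = 1.5,
) -> List[PointSource]:
    """Composite point sources (one per affected sub-watershed) at random
    network positions with log-normal annual TN loads (kg/yr).

    Placement is weighted toward upstream channel (edge weight proportional
    to length times distance-to-outlet**upstream_weight) so a realistic share
    of monitoring sites has at least one source in its upstream area.
    """
    rng = _stage_rng(seed, "sources")
    lengths = np.array([e[2] for e in network.edges])
    node_out = network.distances_to_outlet()
    w = lengths * np.array(
        [(0.5 * (node_out[u] + node_out[v])) ** upstream_weight for u, v, _ in network.edges]
    )
    picks = rng.choice(len(network.edges), size=n_sources, p=w / w.sum())
    offsets = rng.uniform(0.0, lengths[picks])
    loads = rng.lognormal(load_meanlog, load_sdlog, size=n_sources)
    sources = []
    for i, (k, off, load) in enumerate(zip(picks, offsets, loads)):
        u, v, _ = network.edges[k]
        sources.append(
            PointSource(
                source_id=f"PS{i + 1:02d}", edge_u=u, edge_v=v,
                offset_km=float(off), tn_load=float(load), sub_watershed=f"W{i + 1:02d}",
            )
        )
    return sources


_REQUIRED_SPEC_KEYS = (
    "lulc", "soil", "mean_slope", "area_km2", "rural_pop_density",
    "manure_density", "point_sources",
)


def generate_covariates(
    sites: pd.DataFrame,
    covariate_spec: Mapping[str, dict],
    seed: int,
    network: Optional[StreamNetwork] = None,
    sources: Optional[Sequence[PointSource]] = None,
) -> pd.DataFrame:
    """Fill sub-watershed covariates for every site.

    LULC and hydrologic-soil-group percentages come from Dirichlet draws
    scaled to 100 (compositional closure is exact); rural population and
    manure densities are area-weighted over a synthetic county overlay;
    the point-source covariate is the distance-weighted upstream load when a
    network and sources are supplied, else zero.
    """
    for key in _REQUIRED_SPEC_KEYS:
        if key not in covariate_spec:
            raise ConfigError(f"covariate_spec is missing required entry {key!r}")
    rng = _stage_rng(seed, "covariates")
    n = len(sites)
    out = sites.copy()

    for family in ("lulc", "soil"):
        spec = covariate_spec[family]
        names = list(spec["means"])
        alpha = np.array([spec["means"][k] for k in names]) * spec["concentration"]
        draws = rng.dirichlet(alpha, size=n) * 100.0
        # exact closure: absorb float residue into the largest share
        draws[np.arange(n), draws.argmax(axis=1)] += 100.0 - draws.sum(axis=1)
        for j, name in enumerate(names):
            out[name] = draws[:, j]

    for name in ("mean_slope", "area_km2", "manure_density"):
        spec = covariate_spec[name]
        out[name] = rng.lognormal(spec["meanlog"], spec["sdlog"], size=n)

    # rural population density through the area-weighted county overlay
    spec = covariate_spec["rural_pop_density"]
    n_counties = int(spec.get("n_counties", 10))
    county_density = rng.lognormal(spec["meanlog"], spec["sdlog"], size=n_counties)
    manure_density = out["manure_density"].to_numpy(float)
    fractions = rng.dirichlet(np.full(n_counties, 0.3), size=n)
    out["rural_pop_density"] = [
        area_weighted_density(fractions[i], county_density) for i in range(n)
    ]

    if network is not None and sources is not None:
        node_out = network.distances_to_outlet()
        lengths = network.edge_lengths()

        def d_outlet(eu, ev, off):
            return node_out[ev] + lengths[(eu, ev)] - off

        from .distances import river_cross_distances

        src_pos = pd.DataFrame(
            {
                "site_id": [s.source_id for s in sources],
                "edge_u": [s.edge_u for s in sources],
                "edge_v": [s.edge_v for s in sources],
                "offset_km": [s.offset_km for s in sources],
            }
        )
        d_src_site = river_cross_distances(src_pos, out, network)
        d_src_out = np.array([d_outlet(s.edge_u, s.edge_v, s.offset_km) for s in sources])
        loads = []
        for i, (_, row) in enumerate(out.iterrows()):
            d_site = d_outlet(row["edge_u"], row["edge_v"], row["offset_km"])
            upstream = [
                s
                for j, s in enumerate(sources)
                if abs(d_src_out[j] - (d_site + d_src_site[j, i])) < 1e-6
            ]
            loads.append(cov.distance_weighted_point_load(row, upstream, network))
        out["point_load"] = loads
    else:
        out["point_load"] = 0.0
    return out


# --------------------------------------------------------------------------
# TN simulation
# --------------------------------------------------------------------------

def simulate_tn(
    sites: pd.DataFrame, network: StreamNetwork, config: SimulationConfig
) -> pd.DataFrame:
    """Draw TN observations: ``LnTN = X beta + eps`` with
    ``eps ~ N(0, sigma^2 Omega(d; theta1, theta2))`` under the configured
    distance metric, then ``TN = exp(LnTN)``."""
    X, names = assemble_design_matrix(sites, config.variables)
    beta = np.array(
        [config.beta["intercept"]] + [config.beta[v] for v in config.variables]
    )
    if config.metric == RIVER:
        D = river_distance_matrix(sites, network).values
    else:
        D = euclidean_distance_matrix(sites).values
    mean = X @ beta
    if config.sigma2 == 0.0:
        eps = np.zeros(len(sites))
    else:
        try:
            omega = correlation_matrix(D, config.theta1, config.theta2)
            L = np.linalg.cholesky(omega)
        except Exception as exc:  # FittingError carries the minimum eigenvalue
            raise SimulationError(f"residual covariance not positive definite: {exc}") from exc
        rng = _stage_rng(config.seed, "tn")
        eps = math.sqrt(config.sigma2) * (L @ rng.standard_normal(len(sites)))
    out = sites.copy()
    out["ln_tn"] = mean + eps
    out["tn"] = np.exp(out["ln_tn"])
    return out


def simulate_watershed(config: SimulationConfig):
    """End-to-end convenience: network, sources, sites with covariates and TN.

    Returns ``(network, sites, sources)``.
    """
    network = generate_network(
        config.seed, n_branch_events=config.n_branch_events, region_extent=config.region_extent
    )
    sites = generate_sites(network, config.n_sites, config.seed)
    src_spec = config.covariate_spec["point_sources"]
    sources = generate_point_sources(
        network, config.seed, n_sources=int(src_spec["n_sources"]),
        load_meanlog=src_spec["load_meanlog"], load_sdlog=src_spec["load_sdlog"],
        upstream_weight=float(src_spec.get("upstream_weight", 1.5)),
    )
    sites = generate_covariates(sites, config.covariate_spec, config.seed, network, sources)
    sites = simulate_tn(sites, network, config)
    return network, sites, sources
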