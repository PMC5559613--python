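"""Explanatory-variable construction for the TN regression models.

The covariates fall in four categories: topography (mean slope, area), land
use / land cover composition, hydrologic-soil-group composition, and pollution
sources.  The pollution-source terms are the distance-weighted TN load from
upstream point sources (sum of load over river distance), the area-weighted
rural population density, and the area-weighted animal-manure load density.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .distances import river_cross_distances
from .exceptions import ValidationError
from .network import StreamNetwork

log = logging.getLogger(__name__)

#: site-table column names, one per candidate explanatory variable
LULC_COLUMNS = (
    "cropland_pct", "forestland_pct", "grassland_pct", "urban_dev_pct",
    "rural_dev_pct", "wetland_pct", "shrub_pct", "barren_pct", "road_pct",
    "water_pct",
)
SOIL_COLUMNS = ("soil_a_pct", "soil_b_pct", "soil_c_pct", "soil_d_pct")
TOPO_COLUMNS = ("mean_slope", "area_km2")
SOURCE_COLUMNS = ("point_load", "rural_pop_density", "manure_density")
CANDIDATE_COLUMNS = TOPO_COLUMNS + LULC_COLUMNS + SOIL_COLUMNS + SOURCE_COLUMNS

#: the four variables retained by stepwise selection in the study design
DEFAULT_VARIABLES = ("cropland_pct", "soil_c_pct", "point_load", "rural_pop_density")

#: transform registry applied when assembling the design matrix.  The
#: point-source load uses ln(1 + x): many sites have no upstream point source,
#: so a plain log would be undefined at zero; ln(1+x) is monotone, zero at
#: zero, and asymptotically equal to ln for large loads.
TRANSFORMS = {
    "identity": lambda x: x,
    "log": np.log,
    "log1p": np.log1p,
}
DEFAULT_TRANSFORM_REGISTRY: Dict[str, str] = {
    "point_load": "log1p",
    "rural_pop_density": "log",
    "manure_density": "log",
}

#: minimum river distance (km) used in the distance-weighted load; the
#: load term is singular at zero distance
MIN_SOURCE_DISTANCE_KM = 0.1


@dataclass(frozen=True)
class PointSource:
    """A single or composite point pollution source on the network."""

    source_id: str
    edge_u: object
    edge_v: object
    offset_km: float
    tn_load: float  # kg/yr
    sub_watershed: Optional[str] = None

    def __post_init__(self) -> None:
        if self.tn_load < 0:
            raise ValidationError(f"source {self.source_id!r} has negative TN load")


@dataclass(frozen=True)
class CountyOverlay:
    """Area fractions of counties intersecting each sub-watershed, with the
    county-level densities to be area-averaged."""

    county_ids: Tuple
    rural_pop_density: Tuple[float, ...]   # persons/km^2
    manure_density: Tuple[float, ...]      # kg/(km^2 yr)
    # mapping sub-watershed id -> per-county area fractions (sum to 1)
    fractions: Mapping[object, Tuple[float, ...]]


def _positions_frame(rows: Iterable[Tuple[object, object, object, float]]) -> pd.DataFrame:
    ids, eu, ev, off = zip(*rows)
    return pd.DataFrame(
        {"site_id": ids, "edge_u": eu, "edge_v": ev, "offset_km": off}
    )


def distance_weighted_point_load(
    site: Mapping,
    upstream_sources: Sequence[PointSource],
    network: StreamNetwork,
    min_distance_km: Optional[float] = MIN_SOURCE_DISTANCE_KM,
) -> float:
    """Distance-weighted TN load from upstream point sources at one site.

    Computes ``sum_i TN_i / D_i`` over the upstream sources, with ``D_i`` the
    river distance (km) from source ``i`` to the site.  A source not strictly
    upstream of the site is excluded with a logged warning.  Distances below
    ``min_distance_km`` are clamped to it; with ``min_distance_km=None`` a
    zero-distance source raises instead, pointing at the floor option.
    """
    if not upstream_sources:
        return 0.0
    site_pos = _positions_frame([(site["site_id"], site["edge_u"], site["edge_v"], site["offset_km"])])
    src_pos = _positions_frame(
        [(s.source_id, s.edge_u, s.edge_v, s.offset_km) for s in upstream_sources]
    )
    d_to_site = river_cross_distances(src_pos, site_pos, network)[:, 0]

    # a source is strictly upstream iff its path to the outlet passes through
    # the site: d_outlet(source) == d_outlet(site) + d(source, site)
    node_out = network.distances_to_outlet()
    lengths = network.edge_lengths()

    def d_outlet(edge_u, edge_v, offset):
        return node_out[edge_v] + lengths[(edge_u, edge_v)] - offset

    d_site_out = d_outlet(site["edge_u"], site["edge_v"], site["offset_km"])
    d_src_out = np.array([d_outlet(s.edge_u, s.edge_v, s.offset_km) for s in upstream_sources])

    total = 0.0
    for s, d, d_out in zip(upstream_sources, d_to_site, d_src_out):
        if abs(d_out - (d_site_out + d)) > 1e-6:
            log.warning("source %r is not upstream of site %r; excluded", s.source_id, site["site_id"])
            continue
        if d <= 0:
            if min_distance_km is None:
                raise ValidationError(
                    f"source {s.source_id!r} lies at zero river distance from site "
                    f"{site['site_id']!r}; set min_distance_km to apply a floor"
                )
            d = min_distance_km
        elif min_distance_km is not None and d < min_distance_km:
            d = min_distance_km
        total += s.tn_load / d
    return total


def area_weighted_density(
    fractions: Sequence[float], densities: Sequence[float], atol: float = 1e-6
) -> float:
    """Area-weighted average of county-level densities for one sub-watershed."""
    f = np.asarray(fractions, float)
    d = np.asarray(densities, float)
    if f.shape != d.shape:
        raise ValidationError("fractions and densities differ in length")
    if np.any(f < -atol) or np.any(f > 1 + atol):
        raise ValidationError("area fractions must lie in [0, 1]")
    if abs(f.sum() - 1.0) > atol:
        raise ValidationError(f"area fractions sum to {f.sum():.6f}, not 1")
    return float(f @ d)


def composition_percentages(category_areas: Mapping[str, float]) -> Dict[str, float]:
    """Convert category areas (km^2) to percentages summing to 100."""
    vals = np.array(list(category_areas.values()), float)
    if np.any(vals < 0):
        raise ValidationError("category areas must be non-negative")
    total = vals.sum()
    if total <= 0:
        raise ValidationError("total category area is zero")
    return {k: 100.0 * v / total for k, v in zip(category_areas, vals)}


def assemble_design_matrix(
    sites: pd.DataFrame,
    variables: Sequence[str] = DEFAULT_VARIABLES,
    transform_registry: Optional[Mapping[str, str]] = None,
) -> Tuple[np.ndarray, List[str]]:
    """Build the regression design matrix ``X`` for the given variables.

    The first column is the intercept (all ones).  Variables listed in the
    transform registry are transformed accordingly (``log``, ``log1p``, or
    ``identity``); the registry defaults to log1p for the point-source load
    and log for the density covariates.

    Returns ``(X, column_names)`` with ``column_names[0] == "intercept"``.
    """
    registry = dict(DEFAULT_TRANSFORM_REGISTRY if transform_registry is None else transform_registry)
    n = len(sites)
    cols = [np.ones(n)]
    names = ["intercept"]
    for var in variables:
        if var not in sites.columns:
            raise ValidationError(f"covariate {var!r} missing from site table")
        vals = sites[var].to_numpy(float)
        bad = np.flatnonzero(~np.isfinite(vals))
        if len(bad):
            sid = sites["site_id"].iloc[bad[0]]
            raise ValidationError(f"missing value for covariate {var!r} at site {sid!r}")
        tname = registry.get(var, "identity")
        if tname not in TRANSFORMS:
            raise ValidationError(f"unknown transform {tname!r} for covariate {var!r}")
        with np.errstate(divide="raise", invalid="raise"):
            try:
                tvals = TRANSFORMS[tname](vals)
            except FloatingPointError:
                raise ValidationError(
                    f"transform {tname!r} undefined for covariate {var!r} values"
                ) from None
        cols.append(np.asarray(tvals, float))
        names.append(f"{tname}_{var}" if tname != "identity" else var)
    return np.column_stack(cols), names


def overlay_densities(overlay: CountyOverlay, sub_watershed) -> Tuple[float, float]:
    """Area-weighted (rural population density, manure load density) for one
    sub-watershed from a county overlay."""
    if sub_watershed not in overlay.fractions:
        raise ValidationError(f"sub-watershed {sub_watershed!r} not in overlay")
    f = overlay.fractions[sub_watershed]
    return (
        area_weighted_density(f, overlay.rural_pop_density),
        area_weighted_density(f, overlay.manure_density),
    )
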