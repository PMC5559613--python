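"""File formats, configuration and the end-to-end pipeline.

CSV dialect is fixed: comma separator, dot decimal, UTF-8, mandatory header
row.  Networks round-trip through an edge-list CSV (one row per edge with
both endpoint coordinates) or a GeoJSON FeatureCollection of LineStrings.
The pipeline configuration is a single YAML file with a versioned schema;
unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .covariates import DEFAULT_TRANSFORM_REGISTRY, DEFAULT_VARIABLES, assemble_design_matrix
from .distances import RIVER, STRAIGHT_LINE, euclidean_distance_matrix, river_distance_matrix
from .exceptions import ConfigError, NetworkError, ValidationError
from .model import SpatialGLS, StepwiseLinearRegression, profile_surface
from .network import StreamNetwork
from .prediction import (
    ClassThresholds,
    classify_tn,
    cross_validate,
    generate_prediction_sites,
    predict_sites,
)
from .synthetic import SimulationConfig, simulate_watershed

log = logging.getLogger(__name__)

NETWORK_COLUMNS = ("edge_u", "edge_v", "u_x", "u_y", "v_x", "v_y", "length_km")
REQUIRED_SITE_COLUMNS = ("site_id", "x", "y")


# --------------------------------------------------------------------------
# site tables
# --------------------------------------------------------------------------

def read_site_table(path) -> pd.DataFrame:
    """Read and validate a site-table CSV.

    Required columns: site_id, x, y.  Network position (edge_u, edge_v,
    offset_km), covariates and tn are optional (tn is absent for prediction
    targets).  Negative or non-numeric TN values are rejected with the row
    named; unknown columns pass through with a warning.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in REQUIRED_SITE_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"site table {path} lacks required column {col!r}")
    known = set(REQUIRED_SITE_COLUMNS) | {
        "edge_u", "edge_v", "offset_km", "tn", "ln_tn", "snap_km",
    }
    from .covariates import CANDIDATE_COLUMNS

    known |= set(CANDIDATE_COLUMNS)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        warnings.warn(f"site table {path}: ignoring unknown column(s) {unknown}")
    numeric = [c for c in df.columns if c not in ("site_id", "edge_u", "edge_v")]
    for col in numeric:
        try:
            df[col] = pd.to_numeric(df[col])
        except (TypeError, ValueError):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValidationError(
                f"non-numeric value in column {col!r} at row {row} of {path}"
            ) from None
    if "tn" in df.columns:
        neg = df.index[df["tn"] < 0]
        if len(neg):
            raise ValidationError(f"negative TN at row {neg[0]} of {path}")
    return df


def write_site_table(sites: pd.DataFrame, path) -> None:
    # %.17g guarantees float64 round-trips exactly
    sites.to_csv(path, index=False, float_format="%.17g")


def read_point_sources(path):
    """Read a point-source CSV: source_id, edge_u, edge_v, offset_km, tn_load
    (kg/yr) and optional sub_watershed."""
    from .covariates import PointSource

    df = pd.read_csv(path, float_precision="round_trip")
    required = ("source_id", "edge_u", "edge_v", "offset_km", "tn_load")
    for col in required:
        if col not in df.columns:
            raise ValidationError(f"point-source file {path} lacks column {col!r}")
    return [
        PointSource(
            source_id=str(r["source_id"]),
            edge_u=_node_id(r["edge_u"]),
            edge_v=_node_id(r["edge_v"]),
            offset_km=float(r["offset_km"]),
            tn_load=float(r["tn_load"]),
            sub_watershed=str(r["sub_watershed"]) if "sub_watershed" in df.columns else None,
        )
        for _, r in df.iterrows()
    ]


# --------------------------------------------------------------------------
# networks
# --------------------------------------------------------------------------

def write_network(network: StreamNetwork, path) -> None:
    """Write the network as an edge-list CSV with endpoint coordinates."""
    rows = []
    for u, v, length in network.edges:
        (ux, uy), (vx, vy) = network.nodes[u], network.nodes[v]
        rows.append((u, v, ux, uy, vx, vy, length))
    pd.DataFrame(rows, columns=NETWORK_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_network(path) -> StreamNetwork:
    """Read a network from edge-list CSV or GeoJSON (by file suffix).

    The outlet is inferred as the unique node without a downstream edge;
    cycles and disconnections raise with the offending nodes listed.
    """
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        return _read_network_geojson(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in NETWORK_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"network file {path} lacks column {col!r}")
    nodes: Dict = {}
    edges = []
    for _, r in df.iterrows():
        u, v = _node_id(r["edge_u"]), _node_id(r["edge_v"])
        nodes[u] = (float(r["u_x"]), float(r["u_y"]))
        nodes[v] = (float(r["v_x"]), float(r["v_y"]))
        edges.append((u, v, float(r["length_km"])))
    outlet = _infer_outlet(edges)
    return StreamNetwork(nodes=nodes, edges=edges, outlet=outlet)


def _node_id(value):
    """Node ids are integers when they look integral, else strings."""
    try:
        f = float(value)
    except (TypeError, ValueError):
        return str(value)
    return int(f) if f.is_integer() else str(value)


def _infer_outlet(edges) -> object:
    ups = {u for u, _, _ in edges}
    downs = {v for _, v, _ in edges}
    sinks = sorted(downs - ups)
    if len(sinks) != 1:
        raise NetworkError(f"expected exactly one outlet, found candidates {sinks}")
    return sinks[0]


def write_network_geojson(network: StreamNetwork, path) -> None:
    """GeoJSON FeatureCollection of LineString edges (coordinates in km)."""
    features = []
    for u, v, length in network.edges:
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [list(network.nodes[u]), list(network.nodes[v])],
                },
                "properties": {"edge_u": u, "edge_v": v, "length_km": length},
            }
        )
    obj = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(obj, indent=1))


def _read_network_geojson(path) -> StreamNetwork:
    obj = json.loads(Path(path).read_text())
    nodes: Dict = {}
    edges = []
    for feat in obj.get("features", []):
        geom = feat.get("geometry", {})
        if geom.get("type") != "LineString":
            continue
        props = feat.get("properties", {})
        u, v = props["edge_u"], props["edge_v"]
        cu, cv = geom["coordinates"][0], geom["coordinates"][-1]
        nodes[u] = (float(cu[0]), float(cu[1]))
        nodes[v] = (float(cv[0]), float(cv[1]))
        edges.append((u, v, float(props["length_km"])))
    return StreamNetwork(nodes=nodes, edges=edges, outlet=_infer_outlet(edges))


# --------------------------------------------------------------------------
# distance matrices and fits
# --------------------------------------------------------------------------

def write_distance_matrix(D, path) -> None:
    D.to_frame().to_csv(path, index_label="site_id")


def read_distance_matrix(path, metric: str = "unknown"):
    """Read a distance matrix CSV (site-id header row and column)."""
    from .distances import DistanceMatrix

    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return DistanceMatrix(list(df.columns), df.to_numpy(float), metric)


def write_predictions_geojson(predictions: pd.DataFrame, path) -> None:
    """GeoJSON Point export of classified predictions (coordinates in km)."""
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [r["x"], r["y"]]},
            "properties": {
                "site_id": r["site_id"],
                "tn_pred": r["tn_pred"],
                "wq_class": r["wq_class"],
            },
        }
        for _, r in predictions.iterrows()
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}, indent=1))


def fit_to_dict(fit, metric: Optional[str] = None, names: Optional[Sequence[str]] = None) -> dict:
    """Serializable summary of a fitted model."""
    if isinstance(fit, SpatialGLS):
        return {
            "model": "spatial",
            "metric": metric,
            "coefficients": dict(zip(fit.feature_names_ or [], map(float, fit.beta_)))
            if fit.feature_names_
            else [float(b) for b in fit.beta_],
            "theta1": fit.theta1_,
            "theta2_km": fit.theta2_,
            "sigma2": fit.sigma2_,
            "log_likelihood": fit.log_likelihood_,
            "residuals": [float(r) for r in fit.residuals_],
            "transform_registry": dict(DEFAULT_TRANSFORM_REGISTRY),
        }
    if isinstance(fit, StepwiseLinearRegression):
        return {
            "model": "ols",
            "selected": fit.selected_,
            "intercept": fit.intercept_,
            "coefficients": dict(zip(fit.selected_, map(float, fit.coef_))),
            "pvalues": fit.pvalues_,
            "r2": fit.rsquared_,
            "sigma2": fit.sigma2_,
            "vif": fit.vif_,
            "breusch_pagan_p": fit.het_pvalue_,
            "diagnostics_ok": fit.diagnostics_ok_,
        }
    raise ValidationError(f"cannot serialize fit of type {type(fit).__name__}")


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

_SCHEMA = {
    "version": int,
    "seed": int,
    "simulate": dict,
    "model": dict,
    "predict": dict,
    "thresholds": list,
    "paths": dict,
}
_SIMULATE_KEYS = {
    "n_sites", "theta1", "theta2", "sigma2", "metric", "n_branch_events", "region_extent",
}
_MODEL_KEYS = {"alpha", "m_neighbors", "metrics", "variables", "grid_size", "fixed_fit"}
_PREDICT_KEYS = {"spacing_km"}
_PATH_KEYS = {"sites", "network"}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``load_config``)."""

    seed: int = 0
    version: int = 1
    simulate: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    predict: dict = field(default_factory=dict)
    thresholds: Tuple[float, ...] = (0.2, 0.5, 1.0, 1.5, 2.0)
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ClassThresholds(tuple(self.thresholds))  # reuse its invariants
        for key, allowed in (
            (self.simulate, _SIMULATE_KEYS),
            (self.model, _MODEL_KEYS),
            (self.predict, _PREDICT_KEYS),
            (self.paths, _PATH_KEYS),
        ):
            unknown = set(key) - allowed
            if unknown:
                raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        for p in self.paths.values():
            if not Path(p).exists():
                raise ConfigError(f"configured path does not exist: {p}")


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - set(_SCHEMA)
    if unknown:
        raise ConfigError(f"unknown top-level config key(s): {sorted(unknown)}")
    if raw.get("version", 1) != 1:
        raise ConfigError(f"unsupported config version {raw.get('version')}")
    return PipelineConfig(**raw)


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the full analysis and write the artifact bundle.

    Stages: obtain data (synthetic by default, or from configured paths),
    compute both distance matrices, stepwise OLS, spatial fits under both
    metrics, leave-one-out cross-validation for the three models, spatial
    prediction on regularly spaced sites with class assignment, and a profile
    surface for the river-distance model.  A manifest records the config hash
    and package versions; outputs are deterministic given the seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    events: list = []

    def stage(name, **info):
        log.info("stage %s: %s", name, info)
        events.append({"stage": name, **info})

    mcfg = config.model
    metrics = mcfg.get("metrics", [STRAIGHT_LINE, RIVER])
    variables = tuple(mcfg.get("variables", DEFAULT_VARIABLES))
    alpha = float(mcfg.get("alpha", 0.05))
    m = int(mcfg.get("m_neighbors", 8))
    thresholds = ClassThresholds(tuple(config.thresholds))

    if config.paths:
        sites = read_site_table(config.paths["sites"])
        network = read_network(config.paths["network"])
        sources = None
    else:
        sim = SimulationConfig(seed=config.seed, **config.simulate)
        network, sites, sources = simulate_watershed(sim)

    stage("data", n_sites=len(sites), total_length_km=round(network.total_length, 3),
          source="files" if config.paths else "synthetic")
    write_site_table(sites, out / "sites.csv")
    write_network(network, out / "network.csv")
    write_network_geojson(network, out / "network.geojson")

    D = {
        STRAIGHT_LINE: euclidean_distance_matrix(sites),
        RIVER: river_distance_matrix(sites, network),
    }
    for metric, mat in D.items():
        write_distance_matrix(mat, out / f"distances_{metric.replace('-', '_')}.csv")

    y = np.log(sites["tn"].to_numpy(float))
    from .covariates import CANDIDATE_COLUMNS, DEFAULT_TRANSFORM_REGISTRY, TRANSFORMS

    candidates = [c for c in CANDIDATE_COLUMNS if c in sites.columns]
    cand_frame = pd.DataFrame(
        {
            c: TRANSFORMS[DEFAULT_TRANSFORM_REGISTRY.get(c, "identity")](sites[c].to_numpy(float))
            for c in candidates
        }
    )
    ols = StepwiseLinearRegression(alpha=alpha).fit(cand_frame, y)
    stage("stepwise_ols", selected=ols.selected_, r2=round(ols.rsquared_, 6))
    (out / "ols_fit.json").write_text(json.dumps(fit_to_dict(ols), indent=1))

    X, names = assemble_design_matrix(sites, variables)
    fits = {}
    for metric in metrics:
        fit = SpatialGLS(
            grid_size=int(mcfg.get("grid_size", 25)), n_neighbors=m
        ).fit(X, y, D=D[metric].values, feature_names=names)
        fits[metric] = fit
        tag = metric.replace("-", "_")
        stage("spatial_fit", metric=metric, theta1=round(fit.theta1_, 6),
              theta2_km=round(fit.theta2_, 3))
        (out / f"spatial_fit_{tag}.json").write_text(
            json.dumps(fit_to_dict(fit, metric=metric), indent=1)
        )

    if RIVER in fits:
        fit = fits[RIVER]
        t1g = np.linspace(0.0, 1.0, 25)
        t2g = np.geomspace(1.0, 4.0 * D[RIVER].values.max(), 25)
        surf = profile_surface(X, y, D[RIVER].values, t1g, t2g)
        surf.to_csv(out / "profile_surface_river.csv", index=False)

    cv_summaries = {}
    frame, summary = cross_validate(
        sites, D[RIVER], "ols", m=m, variables=variables, thresholds=thresholds
    )
    frame.to_csv(out / "cv_ols.csv", index=False)
    cv_summaries["ols"] = summary
    for metric in metrics:
        frame, summary = cross_validate(
            sites, D[metric], "spatial", m=m, variables=variables,
            fixed_fit=bool(mcfg.get("fixed_fit", False)), thresholds=thresholds,
            estimator_params={"grid_size": int(mcfg.get("grid_size", 25))},
        )
        tag = metric.replace("-", "_")
        frame.to_csv(out / f"cv_spatial_{tag}.csv", index=False)
        cv_summaries[f"spatial_{tag}"] = summary
        stage("cross_validation", model=f"spatial_{tag}", r2=round(summary["r2"], 6))
    (out / "cv_summary.json").write_text(json.dumps(cv_summaries, indent=1))

    spacing = float(config.predict.get("spacing_km", 10.0))
    targets = generate_prediction_sites(network, spacing)
    if sources is not None:
        from .synthetic import generate_covariates

        sim = SimulationConfig(seed=config.seed, **config.simulate)
        targets = generate_covariates(targets, sim.covariate_spec, config.seed, network, sources)
    best_metric = RIVER if RIVER in fits else metrics[0]
    predictions = predict_sites(
        fits[best_metric], targets, sites, network=network, m=m,
        metric=best_metric, variables=variables, thresholds=thresholds,
    )
    predictions.to_csv(out / "predictions.csv", index=False)
    class_counts = predictions["wq_class"].value_counts().to_dict()
    stage("prediction", n_targets=len(predictions), class_counts=class_counts)
    (out / "classification.json").write_text(json.dumps(class_counts, indent=1))
    (out / "events.jsonl").write_text(
        "".join(json.dumps(e, default=str) + "\n" for e in events)
    )

    manifest = {
        "config": asdict(config),
        "config_sha256": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True, default=list).encode()
        ).hexdigest(),
        "streamtn_version": __version__,
        "numpy_version": np.__version__,
        "outputs": sorted(p.name for p in out.iterdir()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=list))
    return {
        "ols": ols,
        "spatial": fits,
        "cv": cv_summaries,
        "predictions": predictions,
        "class_counts": class_counts,
        "out_dir": str(out),
    }
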