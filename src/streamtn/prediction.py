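"""Prediction at unmonitored sites, cross-validation and class assignment.

Prediction follows the regression-plus-kriged-residual form
``Yhat_0 = X_0 beta_hat + eps_hat_0`` where ``eps_hat_0 = sum_i lambda_i
eps_hat_i`` is the ordinary-kriging estimate of the residual from the ``m``
nearest monitoring sites, with weights constrained to sum to one.  Kriging is
formulated in correlations: under ordinary kriging with covariance
proportional to correlation the sill cancels from the bordered system, so
weights from correlations and covariances coincide.

Back-transformation to concentration is plain ``exp`` (no lognormal bias
correction by default, mirroring the modelling choice of predicting the
median); an optional correction is available.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import linalg

from .covariates import DEFAULT_TRANSFORM_REGISTRY, DEFAULT_VARIABLES, assemble_design_matrix
from .distances import (
    RIVER,
    STRAIGHT_LINE,
    DistanceMatrix,
    euclidean_distance_matrix,
    river_cross_distances,
    river_distance_matrix,
)
from .exceptions import FittingError, ValidationError
from .model import SpatialGLS, correlation_matrix, exponential_correlation
from .network import StreamNetwork

log = logging.getLogger(__name__)

CLASS_LABELS = ("I", "II", "III", "IV", "V")
WORSE_THAN_V = "worse-than-V"


@dataclass(frozen=True)
class ClassThresholds:
    """Ordered TN upper bounds (mg/L) for surface-water classes I-V.

    Defaults follow the GB3838-2002 total-nitrogen limits; a concentration
    above the last bound (2 mg/L) is labelled worse than Class V.  A value
    exactly at a bound belongs to the better class ("exceeds" is strict).
    """

    bounds: Tuple[float, ...] = (0.2, 0.5, 1.0, 1.5, 2.0)

    def __post_init__(self) -> None:
        if len(self.bounds) != len(CLASS_LABELS):
            raise ValidationError(f"expected {len(CLASS_LABELS)} class bounds")
        if any(b <= a for a, b in zip(self.bounds, self.bounds[1:])):
            raise ValidationError("class bounds must be strictly increasing")


DEFAULT_THRESHOLDS = ClassThresholds()


def classify_tn(tn: float, thresholds: ClassThresholds = DEFAULT_THRESHOLDS) -> str:
    """Water-quality class of a TN concentration (mg/L)."""
    if tn < 0:
        raise ValidationError(f"negative TN concentration {tn}")
    for label, bound in zip(CLASS_LABELS, thresholds.bounds):
        if tn <= bound:
            return label
    return WORSE_THAN_V


def classification_confusion(
    observed: Sequence[str], predicted: Sequence[str]
) -> Dict[str, int]:
    """2x2 tally on the {V or better, worse than V} split.

    Returns counts of correct classifications and the two error kinds:
    ``v_or_better_as_worse`` and ``worse_as_v_or_better``.
    """
    if len(observed) != len(predicted):
        raise ValidationError("label lists differ in length")
    worse = lambda c: c == WORSE_THAN_V
    counts = {"correct": 0, "v_or_better_as_worse": 0, "worse_as_v_or_better": 0}
    for o, p in zip(observed, predicted):
        if worse(o) == worse(p):
            counts["correct"] += 1
        elif worse(p):
            counts["v_or_better_as_worse"] += 1
        else:
            counts["worse_as_v_or_better"] += 1
    return counts


# --------------------------------------------------------------------------
# ordinary kriging
# --------------------------------------------------------------------------

def kriging_weights(
    neighbor_corr: np.ndarray, target_corr: np.ndarray, jitter: float = 1e-10
) -> Tuple[np.ndarray, float]:
    """Solve the ordinary-kriging system in correlation form.

    The bordered system ``[[C, 1], [1', 0]] [lambda; mu] = [c0; 1]`` enforces
    the unbiasedness constraint ``sum(lambda) = 1`` through the Lagrange
    multiplier ``mu``.  Returns ``(lambda, mu)``.
    """
    C = np.asarray(neighbor_corr, dtype=float)
    c0 = np.asarray(target_corr, dtype=float).ravel()
    m = len(c0)
    if m < 1:
        raise ValidationError("need at least one neighbor")
    if C.shape != (m, m):
        raise ValidationError("neighbor correlation matrix shape mismatch")
    A = np.zeros((m + 1, m + 1))
    A[:m, :m] = C
    A[:m, m] = 1.0
    A[m, :m] = 1.0
    b = np.append(c0, 1.0)
    try:
        sol = linalg.solve(A, b, assume_a="sym", check_finite=False)
    except linalg.LinAlgError:
        A[:m, :m] += jitter * np.eye(m)
        try:
            sol = linalg.solve(A, b, assume_a="sym", check_finite=False)
        except linalg.LinAlgError:
            raise FittingError("singular ordinary-kriging system") from None
    return sol[:m], float(sol[m])


def krige_residual(
    fit: SpatialGLS, target_distances: np.ndarray, m: int
) -> Tuple[float, np.ndarray, np.ndarray]:
    """Ordinary-kriging residual estimate at one target.

    ``target_distances`` holds the target's distances (km) to every site of
    the fit, in the fit's site order.  Returns ``(eps0, weights, neighbor
    indices)`` where the neighbors are the ``m`` nearest fit sites (distance
    ties broken by ascending index).
    """
    d0 = np.asarray(target_distances, dtype=float).ravel()
    n = len(fit.y_)
    if d0.shape != (n,):
        raise ValidationError("target distance vector length mismatch")
    if not 1 <= m <= n:
        raise ValidationError(f"m={m} outside [1, {n}]")
    order = np.lexsort((np.arange(n), d0))[:m]
    C = correlation_matrix(fit.D_[np.ix_(order, order)], fit.theta1_, fit.theta2_)
    c0 = np.atleast_1d(exponential_correlation(d0[order], fit.theta1_, fit.theta2_))
    lam, _ = kriging_weights(C, c0)
    return float(lam @ fit.residuals_[order]), lam, order


# --------------------------------------------------------------------------
# site-level prediction
# --------------------------------------------------------------------------

def generate_prediction_sites(network: StreamNetwork, spacing_km: float) -> pd.DataFrame:
    """Deterministic prediction sites every ``spacing_km`` of arc length.

    Sites sit at along-network distances 0, s, 2s, ... from the outlet on
    every root-to-leaf path; positions on shared path segments are emitted
    once.  A spacing larger than the whole network yields the outlet site
    only, with a warning.
    """
    if spacing_km <= 0:
        raise ValidationError("spacing must be positive")
    if spacing_km > network.total_length:
        warnings.warn("spacing exceeds total network length; only the outlet site generated")
    node_out = network.distances_to_outlet()
    rows = []
    # outlet itself (t = 0): place on any edge ending at the outlet
    for u, v, length in network.edges:
        if v == network.outlet:
            rows.append((u, v, length))
            break
    for u, v, length in network.edges:
        t_lo = node_out[v]           # arc distance of the downstream end
        t_hi = t_lo + length         # arc distance of the upstream end
        k = int(np.floor(t_lo / spacing_km)) + 1
        while k * spacing_km <= t_hi + 1e-9:
            t = k * spacing_km
            offset = length - (t - t_lo)
            rows.append((u, v, min(max(offset, 0.0), length)))
            k += 1
    sites = pd.DataFrame(rows, columns=["edge_u", "edge_v", "offset_km"])
    coords = [network.interpolate(u, v, o) for u, v, o in rows]
    sites["x"] = [c[0] for c in coords]
    sites["y"] = [c[1] for c in coords]
    sites.insert(0, "site_id", [f"P{i:03d}" for i in range(len(sites))])
    return sites


def predict_sites(
    fit: SpatialGLS,
    targets: pd.DataFrame,
    monitoring_sites: pd.DataFrame,
    network: Optional[StreamNetwork] = None,
    m: int = 8,
    metric: str = RIVER,
    variables: Sequence[str] = DEFAULT_VARIABLES,
    transform_registry=None,
    thresholds: ClassThresholds = DEFAULT_THRESHOLDS,
    bias_correct: bool = False,
) -> pd.DataFrame:
    """Predict LnTN/TN and the water-quality class at target sites.

    For each target: ``Yhat_0 = X_0 beta_hat + eps_hat_0`` with the residual
    kriged from the ``m`` nearest monitoring sites under ``metric``; TN is the
    back-transformed ``exp(Yhat_0)`` (optionally with a lognormal
    half-variance correction).  Returns one record per target with the kriged
    residual, neighbor ids, weights, TN and class.
    """
    X0, _ = assemble_design_matrix(targets, variables, transform_registry)
    if metric == RIVER:
        if network is None:
            raise ValidationError("river-metric prediction needs the stream network")
        D0 = river_cross_distances(targets, monitoring_sites, network)
    elif metric == STRAIGHT_LINE:
        tx = targets[["x", "y"]].to_numpy(float)
        mx = monitoring_sites[["x", "y"]].to_numpy(float)
        D0 = np.sqrt(((tx[:, None, :] - mx[None, :, :]) ** 2).sum(axis=2))
    else:
        raise ValidationError(f"unknown metric {metric!r}")

    site_ids = list(monitoring_sites["site_id"])
    records = []
    for i, (_, row) in enumerate(targets.iterrows()):
        eps0, lam, order = krige_residual(fit, D0[i], m)
        y0 = float(X0[i] @ fit.beta_) + eps0
        if bias_correct:
            y0_adj = y0 + 0.5 * fit.sigma2_ * (1.0 - float(lam @ lam))
            tn = float(np.exp(y0_adj))
        else:
            tn = float(np.exp(y0))
        records.append(
            {
                "site_id": row["site_id"],
                "x": row.get("x", np.nan),
                "y": row.get("y", np.nan),
                "ln_tn_pred": y0,
                "kriged_residual": eps0,
                "tn_pred": tn,
                "wq_class": classify_tn(tn, thresholds),
                "neighbor_ids": ";".join(str(site_ids[j]) for j in order),
                "kriging_weights": ";".join(f"{w:.6g}" for w in lam),
            }
        )
    return pd.DataFrame(records)


# --------------------------------------------------------------------------
# leave-one-out cross-validation
# --------------------------------------------------------------------------

def cross_validate(
    sites: pd.DataFrame,
    D: DistanceMatrix,
    model_kind: str = "spatial",
    m: int = 8,
    variables: Sequence[str] = DEFAULT_VARIABLES,
    transform_registry=None,
    fixed_fit: bool = False,
    estimator_params: Optional[dict] = None,
    thresholds: ClassThresholds = DEFAULT_THRESHOLDS,
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Leave-one-out cross-validation of the OLS or spatial model.

    Each site is held out in turn and predicted from the remaining sites: by
    regression only (``model_kind="ols"``) or by regression plus ordinary
    kriging of the residuals at the ``m`` nearest remaining sites
    (``model_kind="spatial"``).  By default the model (including theta) is
    re-estimated on the retained sites at every fold; ``fixed_fit=True``
    instead reuses one full-data fit and only re-krigs, the lighter variant.

    Returns the per-site prediction frame and a summary with R^2 (squared
    Pearson correlation of observed vs predicted LnTN), RMSE on the LnTN
    scale, and the binary classification tally against ``thresholds``.
    """
    if model_kind not in ("ols", "spatial"):
        raise ValidationError(f"unknown model kind {model_kind!r}")
    if "tn" not in sites.columns:
        raise ValidationError("cross-validation needs observed TN concentrations")
    n = len(sites)
    if n < m + 2:
        raise ValidationError(f"need at least m+2={m + 2} sites")
    X, names = assemble_design_matrix(sites, variables, transform_registry)
    y = np.log(sites["tn"].to_numpy(float))
    Dv = D.values
    params = dict(estimator_params or {})
    params.setdefault("n_neighbors", m)

    full_fit = None
    if model_kind == "spatial" and fixed_fit:
        full_fit = SpatialGLS(**params).fit(X, y, D=Dv, feature_names=names)

    preds = np.full(n, np.nan)
    failed: List[int] = []
    for i in range(n):
        keep = np.array([j for j in range(n) if j != i])
        try:
            if model_kind == "ols":
                beta, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
                preds[i] = float(X[i] @ beta)
            else:
                if fixed_fit:
                    fit = SpatialGLS(
                        theta1=full_fit.theta1_, theta2=full_fit.theta2_, **{
                            k: v for k, v in params.items() if k not in ("theta1", "theta2")
                        }
                    ).fit(X[keep], y[keep], D=Dv[np.ix_(keep, keep)], feature_names=names)
                else:
                    fit = SpatialGLS(**params).fit(
                        X[keep], y[keep], D=Dv[np.ix_(keep, keep)], feature_names=names
                    )
                eps0, _, _ = krige_residual(fit, Dv[i, keep], m)
                preds[i] = float(X[i] @ fit.beta_) + eps0
        except FittingError as exc:  # pragma: no cover - defensive
            log.warning("fold %d failed: %s", i, exc)
            failed.append(i)
    ok = np.flatnonzero(np.isfinite(preds))
    if len(failed):
        warnings.warn(f"{len(failed)} cross-validation fold(s) failed; summary uses the rest")

    obs, est = y[ok], preds[ok]
    r = np.corrcoef(obs, est)[0, 1] if len(ok) > 1 else np.nan
    rmse = float(np.sqrt(np.mean((obs - est) ** 2)))
    obs_cls = [classify_tn(t, thresholds) for t in np.exp(obs)]
    est_cls = [classify_tn(t, thresholds) for t in np.exp(est)]
    confusion = classification_confusion(obs_cls, est_cls)

    frame = pd.DataFrame(
        {
            "site_id": sites["site_id"].to_numpy(),
            "ln_tn_obs": y,
            "ln_tn_pred": preds,
            "tn_obs": np.exp(y),
            "tn_pred": np.exp(preds),
        }
    )
    summary = {
        "model": model_kind,
        "n_folds": int(len(ok)),
        "r2": float(r**2) if np.isfinite(r) else float("nan"),
        "rmse": rmse,
        **confusion,
    }
    return frame, summary
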