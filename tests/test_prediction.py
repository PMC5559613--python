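"""Kriging prediction, cross-validation and class assignment."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from streamtn.covariates import assemble_design_matrix
from streamtn.distances import DistanceMatrix, river_distance_matrix
from streamtn.exceptions import ValidationError
from streamtn.model import SpatialGLS, correlation_matrix, exponential_correlation
from streamtn.prediction import (
    ClassThresholds,
    classification_confusion,
    classify_tn,
    cross_validate,
    generate_prediction_sites,
    krige_residual,
    kriging_weights,
    predict_sites,
)
from streamtn.synthetic import SimulationConfig, simulate_watershed


class TestKrigingWeights:
    def test_single_neighbor_forced_to_one(self):
        lam, _ = kriging_weights(np.array([[1.0]]), np.array([0.4]))
        assert lam == pytest.approx([1.0])

    def test_symmetric_pair_splits_evenly(self):
        C = np.array([[1.0, 0.3], [0.3, 1.0]])
        lam, _ = kriging_weights(C, np.array([0.5, 0.5]))
        assert lam == pytest.approx([0.5, 0.5])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bordered_system_oracle(self, seed):
        rng = np.random.default_rng(seed)
        D = squareform(pdist(rng.uniform(0, 60, size=(3, 2))))
        C = correlation_matrix(D, 0.1, 50.0)
        c0 = exponential_correlation(rng.uniform(1, 60, size=3), 0.1, 50.0)
        lam, mu = kriging_weights(C, c0)
        A = np.zeros((4, 4))
        A[:3, :3] = C
        A[3, :3] = A[:3, 3] = 1.0
        sol = np.linalg.inv(A) @ np.append(c0, 1.0)
        assert np.allclose(lam, sol[:3], atol=1e-9)
        assert mu == pytest.approx(sol[3], abs=1e-9)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            m = int(rng.integers(1, 9))
            D = squareform(pdist(rng.uniform(0, 60, size=(m, 2))))
            C = correlation_matrix(D, float(rng.uniform(0, 1)), 40.0)
            c0 = exponential_correlation(rng.uniform(0.5, 80, size=m), 0.2, 40.0)
            lam, _ = kriging_weights(C, c0)
            assert lam.sum() == pytest.approx(1.0, abs=1e-10)

    def test_covariance_scale_cancels(self):
        """Ordinary kriging weights from correlations equal those from
        covariances sigma^2 * C: the sill cancels in the bordered system."""
        rng = np.random.default_rng(10)
        D = squareform(pdist(rng.uniform(0, 60, size=(4, 2))))
        C = correlation_matrix(D, 0.15, 30.0)
        c0 = exponential_correlation(rng.uniform(1, 60, size=4), 0.15, 30.0)
        lam_corr, _ = kriging_weights(C, c0)
        lam_cov, _ = kriging_weights(2.7 * C, 2.7 * c0)
        assert np.allclose(lam_corr, lam_cov, atol=1e-9)


def _toy_fit(rng, n=12, theta1=0.1, theta2=50.0):
    xy = rng.uniform(0, 80, size=(n, 2))
    D = squareform(pdist(xy))
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    omega = correlation_matrix(D, theta1, theta2)
    y = X @ np.array([1.0, 0.5]) + np.linalg.cholesky(omega) @ rng.normal(size=n)
    return SpatialGLS(theta1=theta1, theta2=theta2).fit(X, y, D=D), X, y, D


class TestKrigeResidual:
    def test_constant_residuals_reproduced(self):
        rng = np.random.default_rng(1)
        fit, X, y, D = _toy_fit(rng)
        fit.residuals_ = np.full(len(y), 3.14)
        eps0, lam, _ = krige_residual(fit, rng.uniform(1, 60, size=len(y)), m=5)
        assert eps0 == pytest.approx(3.14)

    def test_zero_nugget_exact_interpolation(self):
        rng = np.random.default_rng(2)
        fit, X, y, D = _toy_fit(rng, theta1=0.0)
        # target coincides with site 3: distance vector = row 3 of D
        eps0, _, idx = krige_residual(fit, D[3], m=6)
        assert 3 in idx
        assert eps0 == pytest.approx(fit.residuals_[3], abs=1e-8)

    def test_neighbor_count_validated(self):
        rng = np.random.default_rng(3)
        fit, X, y, D = _toy_fit(rng)
        with pytest.raises(ValidationError):
            krige_residual(fit, D[0], m=0)
        with pytest.raises(ValidationError):
            krige_residual(fit, D[0], m=len(y) + 1)


@pytest.fixture(scope="module")
def fitted():
    cfg = SimulationConfig(seed=6, n_sites=25, n_branch_events=10)
    net, sites, sources = simulate_watershed(cfg)
    X, names = assemble_design_matrix(sites)
    D = river_distance_matrix(sites, net)
    fit = SpatialGLS(grid_size=8).fit(X, np.log(sites.tn.to_numpy()), D=D.values,
                                      feature_names=names)
    return net, sites, sources, fit


class TestPredictSites:

    def test_record_fields_and_decomposition(self, fitted):
        net, sites, sources, fit = fitted
        from streamtn.synthetic import DEFAULT_COVARIATE_SPEC, generate_covariates

        targets = generate_prediction_sites(net, 25.0)
        targets = generate_covariates(targets, DEFAULT_COVARIATE_SPEC, 6, net, sources)
        recs = predict_sites(fit, targets, sites, network=net, m=8)
        assert len(recs) == len(targets)
        X0, _ = assemble_design_matrix(targets)
        # prediction minus kriged residual is exactly the regression part
        assert np.allclose(recs.ln_tn_pred - recs.kriged_residual, X0 @ fit.beta_, atol=1e-10)
        # back-transform is monotone
        order = np.argsort(recs.ln_tn_pred.to_numpy())
        assert (np.diff(recs.tn_pred.to_numpy()[order]) >= 0).all()
        assert all(len(s.split(";")) == 8 for s in recs.neighbor_ids)

    def test_duplicate_of_monitoring_site_zero_nugget(self, fitted):
        net, sites, _, _ = fitted
        X, names = assemble_design_matrix(sites)
        D = river_distance_matrix(sites, net)
        y = np.log(sites.tn.to_numpy())
        fit0 = SpatialGLS(theta1=0.0, theta2=200.0).fit(X, y, D=D.values, feature_names=names)
        target = sites.iloc[[4]].copy()
        recs = predict_sites(fit0, target, sites, network=net, m=8)
        assert recs.ln_tn_pred.iloc[0] == pytest.approx(y[4], abs=1e-8)


class TestPredictionSiteGeneration:
    def test_arc_spacing_on_single_edge(self, long_edge_network):
        sites = generate_prediction_sites(long_edge_network, 10.0)
        assert len(sites) == 3  # arc distances 0, 10, 20 on a 25-km edge
        d_out = sorted(25.0 - sites.offset_km)  # distance of each site to outlet
        assert d_out == pytest.approx([0.0, 10.0, 20.0])

    def test_spacing_larger_than_network(self, single_edge_network):
        with pytest.warns(UserWarning, match="spacing"):
            sites = generate_prediction_sites(single_edge_network, 50.0)
        assert len(sites) == 1

    def test_deterministic(self, y_network):
        a = generate_prediction_sites(y_network, 4.0)
        b = generate_prediction_sites(y_network, 4.0)
        pd.testing.assert_frame_equal(a, b)

    def test_positive_spacing_required(self, y_network):
        with pytest.raises(ValidationError):
            generate_prediction_sites(y_network, 0.0)


class TestCrossValidation:
    def test_noiseless_data_perfectly_predicted(self):
        cfg = SimulationConfig(seed=7, n_sites=20, sigma2=0.0, n_branch_events=8)
        net, sites, _ = simulate_watershed(cfg)
        D = river_distance_matrix(sites, net)
        for kind in ("ols", "spatial"):
            _, summary = cross_validate(
                sites, D, kind, m=5, estimator_params={"grid_size": 5}
            )
            assert summary["r2"] == pytest.approx(1.0, abs=1e-6)
            assert summary["rmse"] == pytest.approx(0.0, abs=1e-6)

    def test_invariant_to_row_order(self):
        cfg = SimulationConfig(seed=9, n_sites=18, n_branch_events=8)
        net, sites, _ = simulate_watershed(cfg)
        perm = sites.sample(frac=1.0, random_state=1).reset_index(drop=True)
        s1 = cross_validate(sites, river_distance_matrix(sites, net), "spatial", m=5,
                            estimator_params={"grid_size": 6})[1]
        s2 = cross_validate(perm, river_distance_matrix(perm, net), "spatial", m=5,
                            estimator_params={"grid_size": 6})[1]
        # identical up to float summation order inside the optimizer
        assert s1["r2"] == pytest.approx(s2["r2"], abs=1e-6)
        assert s1["rmse"] == pytest.approx(s2["rmse"], abs=1e-6)

    def test_requires_observations_and_enough_sites(self):
        cfg = SimulationConfig(seed=7, n_sites=6, n_branch_events=4)
        net, sites, _ = simulate_watershed(cfg)
        D = river_distance_matrix(sites, net)
        with pytest.raises(ValidationError):
            cross_validate(sites.drop(columns="tn"), D, "ols", m=2)
        with pytest.raises(ValidationError):
            cross_validate(sites, D, "ols", m=6)
        with pytest.raises(ValidationError):
            cross_validate(sites, D, "bogus", m=2)


class TestClassification:
    def test_boundary_rule(self):
        assert classify_tn(2.1) == "worse-than-V"
        assert classify_tn(2.0) == "V"  # boundary belongs to the better class
        assert classify_tn(0.9) == "III"
        assert classify_tn(0.0) == "I"

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            classify_tn(-0.1)

    def test_thresholds_validated(self):
        with pytest.raises(ValidationError):
            ClassThresholds(bounds=(0.5, 0.2, 1.0, 1.5, 2.0))
        with pytest.raises(ValidationError):
            ClassThresholds(bounds=(1.0, 2.0))

    def test_confusion_identical_lists(self):
        labels = ["V", "III", "worse-than-V"]
        out = classification_confusion(labels, labels)
        assert out == {"correct": 3, "v_or_better_as_worse": 0, "worse_as_v_or_better": 0}

    def test_confusion_all_wrong_direction(self):
        obs = ["I", "V", "III"]
        pred = ["worse-than-V"] * 3
        out = classification_confusion(obs, pred)
        assert out["v_or_better_as_worse"] == 3
        assert out["correct"] == 0

    def test_confusion_hand_tallied(self):
        obs = ["V", "worse-than-V", "I", "II", "worse-than-V",
               "III", "IV", "worse-than-V", "V", "I"]
        pred = ["V", "V", "I", "worse-than-V", "worse-than-V",
                "III", "IV", "II", "V", "I"]
        out = classification_confusion(obs, pred)
        assert out["correct"] == 7
        assert out["v_or_better_as_worse"] + out["worse_as_v_or_better"] == 3
        assert out["worse_as_v_or_better"] == 2

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            classification_confusion(["V"], ["V", "I"])
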