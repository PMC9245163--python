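"""Residual estimation and the eight-method clustering dispatch."""

import numpy as np
import pytest

from stcarclust import (
    METHODS,
    ClusteringRequest,
    CountData,
    build_partitions_A,
    build_partitions_B,
    estimate_phi_tilde,
    run_clustering,
)
from stcarclust.evaluation import ari


class TestEstimatePhiTilde:
    def test_sir_one_gives_zero_residuals(self):
        E = np.full((4, 3), 10.0)
        data = CountData(Y=E.astype(int), E=E)
        res = estimate_phi_tilde(data)
        assert np.allclose(res.phi_tilde, 0.0)
        assert res.beta_hat[0] == pytest.approx(0.0)

    def test_constant_sir_absorbed_by_intercept(self):
        E = np.full((4, 3), 10.0)
        data = CountData(Y=(2 * E).astype(int), E=E)
        res = estimate_phi_tilde(data)
        # ln(2) is soaked up by the ML intercept, leaving flat residuals
        assert res.beta_hat[0] == pytest.approx(np.log(2.0))
        assert np.allclose(res.phi_tilde, 0.0, atol=1e-12)

    def test_zero_count_continuity_correction(self):
        Y = np.array([[0, 10]])
        E = np.array([[10.0, 10.0]])
        data = CountData(Y=Y, E=E)
        res = estimate_phi_tilde(data)
        b0 = np.log(10 / 20)
        assert res.phi_tilde[0, 0] == pytest.approx(np.log(0.5 / 10.0) - b0)

    def test_covariate_fit_uses_poisson_glm(self, rng):
        n, T = 40, 3
        x = rng.normal(size=(n, T, 1))
        E = np.full((n, T), 50.0)
        eta = 0.3 + 0.5 * x[:, :, 0]
        Y = rng.poisson(E * np.exp(eta))
        data = CountData(Y=Y, E=E, X=x)
        res = estimate_phi_tilde(data)
        assert res.beta_hat[1] == pytest.approx(0.5, abs=0.1)


class TestRunClustering:
    @pytest.mark.parametrize("method", sorted(METHODS))
    def test_k1_is_single_cluster(self, method, rng):
        X = rng.normal(size=(12, 2))
        p = run_clustering(ClusteringRequest(method=method, k=1, data=X, seed=0))
        assert p.n_effective == 1

    @pytest.mark.parametrize("method", sorted(METHODS))
    def test_two_separated_clouds_are_separated(self, method, rng):
        X = np.concatenate([rng.normal(0, 1, (10, 2)), rng.normal(100, 1, (10, 2))])
        truth = np.repeat([1, 2], 10)
        p = run_clustering(ClusteringRequest(method=method, k=2, data=X, seed=0))
        assert ari(truth, p.labels) == pytest.approx(1.0)

    def test_ward_with_k_equals_n_gives_singletons(self, rng):
        X = rng.normal(size=(8, 2))
        p = run_clustering(ClusteringRequest(method="agg_ward", k=8, data=X, seed=0))
        assert p.n_effective == 8

    def test_k_above_n_rejected(self, rng):
        with pytest.raises(ValueError):
            run_clustering(
                ClusteringRequest(method=1, k=9, data=rng.normal(size=(5, 1)), seed=0)
            )

    def test_degenerate_constant_data_collapses_to_one_cluster(self):
        X = np.ones((10, 3))
        for method in sorted(METHODS):
            p = run_clustering(ClusteringRequest(method=method, k=3, data=X, seed=0))
            assert p.n_effective == 1

    def test_canonical_labels_ordered_by_level(self, rng):
        X = np.concatenate(
            [rng.normal(5, 0.1, (5, 1)), rng.normal(-5, 0.1, (5, 1)), rng.normal(0, 0.1, (5, 1))]
        )
        p = run_clustering(ClusteringRequest(method="kmeans", k=3, data=X, seed=0))
        # label 1 = lowest level, label 3 = highest
        assert np.all(p.labels[5:10] == 1)
        assert np.all(p.labels[10:] == 2)
        assert np.all(p.labels[:5] == 3)

    def test_adjacency_never_enters_feature_clustering(self, rng):
        """Consistently permuting rows permutes labels identically.

        Partitions may depend only on feature values, so reordering the
        areas (which scrambles any implicit spatial ordering) must yield the
        equivalent clustering of well-separated data.
        """
        centres = np.repeat([[-6.0], [0.0], [6.0]], 5, axis=0)
        X = np.hstack([centres] * 3) + rng.normal(0, 0.3, size=(15, 3))
        perm = rng.permutation(15)
        for method in sorted(METHODS):
            p1 = run_clustering(ClusteringRequest(method=method, k=3, data=X, seed=3))
            p2 = run_clustering(
                ClusteringRequest(method=method, k=3, data=X[perm], seed=3)
            )
            assert ari(p1.labels[perm], p2.labels) == pytest.approx(1.0)

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(30, 3))
        for method in sorted(METHODS):
            a = run_clustering(ClusteringRequest(method=method, k=4, data=X, seed=7))
            b = run_clustering(ClusteringRequest(method=method, k=4, data=X, seed=7))
            assert np.array_equal(a.labels, b.labels)


class TestPartitionBuilders:
    def test_variant_a_counts(self, rng):
        from stcarclust.stage1 import ResidualSurface

        res = ResidualSurface(phi_tilde=rng.normal(size=(30, 4)), beta_hat=np.zeros(1))
        parts = build_partitions_A(res, M=8, K=10, seed=0)
        assert len(parts) == 72
        assert set(parts) == {(c, k) for c in range(1, 9) for k in range(2, 11)}

    def test_variant_b_counts(self, rng):
        from stcarclust.stage1 import ResidualSurface

        res = ResidualSurface(phi_tilde=rng.normal(size=(30, 7)), beta_hat=np.zeros(1))
        parts = build_partitions_B(res, M=8, K=10, seed=0)
        assert len(parts) == 504

    def test_three_level_surface_recovered_by_kmeans(self, rng):
        from stcarclust.stage1 import ResidualSurface

        levels = np.repeat([-1.0, 0.0, 1.0], 20)
        phi = levels[:, None] + rng.normal(0, 0.05, size=(60, 5))
        res = ResidualSurface(phi_tilde=phi, beta_hat=np.zeros(1))
        parts = build_partitions_A(res, M=1, K=3, seed=0)
        truth = np.repeat([1, 2, 3], 20)
        assert ari(truth, parts[(1, 3)].labels) == pytest.approx(1.0)

    def test_variant_b_sign_grouping_with_kmedoids(self, rng):
        from stcarclust.stage1 import ResidualSurface

        col = np.concatenate([-np.ones(10), np.ones(10)])
        phi = np.tile(col[:, None], (1, 2)) + rng.normal(0, 0.01, size=(20, 2))
        res = ResidualSurface(phi_tilde=phi, beta_hat=np.zeros(1))
        parts = build_partitions_B(res, M=2, K=2, seed=0)
        p = parts[(2, 2, 1)]
        assert ari(np.repeat([1, 2], 10), p.labels) == pytest.approx(1.0)
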