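import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from cellmotion import (build_features, hierarchical_cluster, kmeans_cluster,
                        pca_reduce, silhouette)
from conftest import silhouette_bruteforce


def blobs(n_per=50, centers=((0, 0), (10, 10), (-10, 10)), sd=0.5, seed=0):
    rng = np.random.default_rng(seed)
    pts, labels = [], []
    for i, c in enumerate(centers):
        pts.append(rng.normal(c, sd, size=(n_per, len(c))))
        labels.extend([i] * n_per)
    return np.vstack(pts), np.array(labels)


def metrics_frame(n=60, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "species": rng.choice(["spA", "spB"], n),
        "scenario": rng.choice(["Sc1", "Sc2"], n),
        "ir": rng.uniform(1, 8, n),
        "dr": rng.uniform(0, 1, n),
        "as_speed": rng.uniform(0.001, 0.01, n),
        "alpha": rng.uniform(0.6, 0.9, n),
        "corr_minutes": rng.uniform(1, 16, n),
        "gamma": rng.uniform(1.5, 2.0, n),
        "beta": rng.uniform(1.1, 2.0, n),
        "apen": rng.uniform(0, 0.5, n),
    })


class TestBuildFeatures:
    def test_standardized_columns(self):
        fm = build_features(metrics_frame(), "kinematic")
        np.testing.assert_allclose(fm.values.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(fm.values.std(axis=0), 1, atol=1e-9)
        assert fm.values.shape[1] == 3

    def test_dynamic_set_is_5d(self):
        fm = build_features(metrics_frame(), "dynamic")
        assert fm.columns == ("alpha", "corr_minutes", "gamma", "beta", "apen")

    def test_undefined_rows_dropped_with_count(self):
        df = metrics_frame()
        df.loc[[3, 7], "dr"] = np.nan
        fm = build_features(df, "kinematic")
        assert fm.n_dropped == 2
        assert len(fm.values) == len(df) - 2

    def test_constant_column_rejected(self):
        df = metrics_frame()
        df["dr"] = 0.5
        with pytest.raises(ValueError, match="dr"):
            build_features(df, "kinematic")

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="apen"):
            build_features(metrics_frame().drop(columns=["apen"]), "dynamic")


class TestPca:
    def test_collinear_data_one_component(self):
        df = metrics_frame()
        df["dr"] = 2.0 * df["ir"] + 1.0
        df["as_speed"] = -0.5 * df["ir"]
        fm = build_features(df, "kinematic")
        _, var = pca_reduce(fm, n_components=3)
        assert var[0] == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_gaussian_flat_spectrum(self):
        rng = np.random.default_rng(1)
        df = metrics_frame(n=1000, seed=1)
        for col in ("alpha", "corr_minutes", "gamma", "beta", "apen"):
            df[col] = rng.standard_normal(1000)
        fm = build_features(df, "dynamic")
        _, var = pca_reduce(fm, n_components=5)
        np.testing.assert_allclose(var, 0.2, atol=0.03)

    def test_too_many_components_rejected(self):
        fm = build_features(metrics_frame(), "kinematic")
        with pytest.raises(ValueError):
            pca_reduce(fm, n_components=4)


class TestKMeans:
    def test_planted_blobs_recovered(self):
        pts, truth = blobs()
        sol = kmeans_cluster(pts, k=3, seed=0)
        assert adjusted_rand_score(truth, sol.assignments) >= 0.99
        assert sol.silhouette > 0.8

    def test_deterministic_given_seed(self):
        pts, _ = blobs(seed=2)
        s1 = kmeans_cluster(pts, k=3, seed=5)
        s2 = kmeans_cluster(pts, k=3, seed=5)
        np.testing.assert_array_equal(s1.assignments, s2.assignments)

    def test_k_equals_n_zero_inertia(self):
        pts = np.array([[0.0, 0], [1, 0], [0, 1], [5, 5]])
        sol = kmeans_cluster(pts, k=4, n_init=10, seed=0)
        assert sol.inertia == pytest.approx(0.0, abs=1e-12)

    def test_k1_silhouette_undefined(self):
        pts, _ = blobs(n_per=10)
        sol = kmeans_cluster(pts, k=1, seed=0)
        assert np.isnan(sol.silhouette)

    def test_composition_rows_sum_to_one(self):
        pts, truth = blobs(n_per=30, seed=3)
        labels = pd.DataFrame({"species": np.where(truth == 0, "spA", "spB"),
                               "scenario": "Sc1"})
        sol = kmeans_cluster(pts, k=3, labels=labels, seed=0)
        species_cols = [c for c in sol.composition.columns if c.startswith("species")]
        np.testing.assert_allclose(sol.composition[species_cols].sum(axis=1), 1.0)


class TestSilhouette:
    def test_two_tight_far_pairs(self):
        pts = np.array([[0.0, 0], [0, 0.01], [100, 100], [100, 100.01]])
        assert silhouette(pts, np.array([1, 1, 2, 2])) >= 0.95

    def test_random_labels_near_zero(self):
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((200, 2))
        labels = rng.integers(1, 3, 200)
        assert abs(silhouette(pts, labels)) <= 0.05

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(4)
        pts = rng.standard_normal((150, 3))
        labels = rng.integers(1, 4, 150)
        assert silhouette(pts, labels) == pytest.approx(
            silhouette_bruteforce(pts, labels), abs=1e-12)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette(np.zeros((5, 2)), np.ones(5, dtype=int))


class TestHierarchical:
    def test_planted_blobs_composition(self):
        pts, truth = blobs(seed=5)
        labels = pd.DataFrame({"species": [f"sp{t}" for t in truth]})
        sol = hierarchical_cluster(pts, k=3, labels=labels)
        # every cluster should be pure in species
        species_cols = [c for c in sol.composition.columns if c.startswith("species")]
        assert np.allclose(sol.composition[species_cols].max(axis=1), 1.0)

    def test_k_equals_n_singletons(self):
        pts = np.array([[0.0, 0], [1, 0], [0, 1]])
        sol = hierarchical_cluster(pts, k=3)
        assert len(np.unique(sol.assignments)) == 3

    def test_agrees_with_kmeans_on_blobs(self):
        pts, _ = blobs(seed=6)
        km = kmeans_cluster(pts, k=3, seed=0)
        hc = hierarchical_cluster(pts, k=3)
        assert adjusted_rand_score(km.assignments, hc.assignments) >= 0.95

    def test_bad_linkage_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(np.zeros((5, 2)), k=2, linkage="single")
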