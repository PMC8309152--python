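"""Applicability-domain machinery: PCA ellipse, similarity index, neighbours."""

import numpy as np
import pandas as pd
import pytest

from solqspr.domain import (doa_report, fit_doa, inside_ellipse,
                            nearest_neighbors, project, similarity_index,
                            similarity_matrix)
from solqspr.evaluation import detect_outliers


def _gaussian_cloud(n, m=10, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.normal(0.5, 0.15, size=(n, m)),
                        columns=[f"d{i}" for i in range(m)])


class TestSimilarityIndex:
    def test_identical_vectors(self):
        v = np.linspace(0, 1, 10)
        assert similarity_index(v, v) == 1.0

    def test_opposite_corners(self):
        assert similarity_index(np.zeros(10), np.ones(10)) == pytest.approx(0.0)

    def test_single_coordinate_difference(self):
        a = np.zeros(10)
        b = np.zeros(10)
        b[3] = 1.0
        assert similarity_index(a, b) == pytest.approx(1 - 1 / np.sqrt(10), abs=1e-9)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b = rng.uniform(0, 1, (2, 10))
            s1, s2 = similarity_index(a, b), similarity_index(b, a)
            assert s1 == s2 and 0.0 <= s1 <= 1.0

    def test_induced_distance_triangle_inequality(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            a, b, c = rng.uniform(0, 1, (3, 10))
            dab = 1 - similarity_index(a, b)
            dbc = 1 - similarity_index(b, c)
            dac = 1 - similarity_index(a, c)
            assert dac <= dab + dbc + 1e-12

    def test_literal_variant_flags_negative_radicand(self):
        a = np.zeros(3)
        b = np.ones(3)
        assert np.isnan(similarity_index(a, b, literal=True))
        assert similarity_index(b, a, literal=True) == pytest.approx(
            1 - np.sqrt(3.0) / np.sqrt(3.0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            similarity_index(np.zeros(3), np.zeros(4))


class TestPca:
    def test_toy_scores_match_eigendecomposition(self):
        """3-point, 2-feature table against a brute-force eigenvector oracle."""
        X = pd.DataFrame({"a": [0.0, 1.0, 2.0], "b": [0.0, 0.5, 1.5]})
        model = fit_doa(X)
        C = np.cov(X.to_numpy().T, ddof=1)
        w, V = np.linalg.eigh(C)
        v1 = V[:, np.argmax(w)]
        centered = X.to_numpy() - X.to_numpy().mean(axis=0)
        expected_pc1 = centered @ v1
        got_pc1 = project(model, X)[:, 0]
        # same axis up to sign
        assert np.allclose(got_pc1, expected_pc1, atol=1e-9) or \
            np.allclose(got_pc1, -expected_pc1, atol=1e-9)

    def test_centroid_projects_to_origin(self):
        X = _gaussian_cloud(200, seed=3)
        model = fit_doa(X)
        centroid = pd.DataFrame([X.mean()], columns=X.columns)
        assert np.allclose(project(model, centroid), 0.0, atol=1e-9)

    def test_training_compound_consistency(self):
        X = _gaussian_cloud(50, seed=4)
        model = fit_doa(X)
        np.testing.assert_allclose(project(model, X), model.training_scores,
                                   atol=1e-9)

    def test_isotropic_cloud_equal_variances(self):
        X = _gaussian_cloud(20_000, m=4, seed=5)
        model = fit_doa(X)
        assert np.allclose(model.explained_variance_ratio, 0.25, atol=0.02)

    def test_rank_one_data_single_component(self):
        rng = np.random.default_rng(6)
        t = rng.normal(size=300)
        X = pd.DataFrame({"a": t, "b": 2 * t, "c": -t})
        model = fit_doa(X)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_projection_contracts_norms(self):
        """Scores in the PC1-2 plane are never longer than the centred vector."""
        X = _gaussian_cloud(100, seed=7)
        model = fit_doa(X)
        centred = X.to_numpy() - model.mean
        norms = np.linalg.norm(centred, axis=1)
        score_norms = np.linalg.norm(project(model, X), axis=1)
        assert np.all(score_norms <= norms + 1e-9)

    def test_too_few_compounds_rejected(self):
        with pytest.raises(ValueError):
            fit_doa(_gaussian_cloud(2, seed=8))

    def test_column_mismatch_rejected(self):
        model = fit_doa(_gaussian_cloud(30, seed=9))
        with pytest.raises(ValueError, match="missing"):
            project(model, pd.DataFrame({"zz": [1.0]}))


class TestEllipse:
    def test_origin_inside(self):
        model = fit_doa(_gaussian_cloud(500, seed=10))
        assert inside_ellipse(model, np.array([[0.0, 0.0]]))[0]

    def test_self_coverage_near_95pct(self):
        model = fit_doa(_gaussian_cloud(10_000, seed=11))
        frac = inside_ellipse(model, model.training_scores).mean()
        assert 0.93 <= frac <= 0.97

    def test_far_point_outside(self):
        model = fit_doa(_gaussian_cloud(500, seed=12))
        far = model.training_scores.max(axis=0) * 50
        assert not inside_ellipse(model, far[None, :])[0]


class TestNeighbors:
    def test_identical_query_is_own_neighbor(self):
        X = _gaussian_cloud(30, seed=13)
        y = np.arange(30.0)
        ids = [f"c{i}" for i in range(30)]
        nb = nearest_neighbors(X.iloc[4], X, y, ids, k=1)
        assert nb.neighbors["compound_id"].tolist() == ["c4"]
        assert nb.neighbors["similarity"].iloc[0] == pytest.approx(1.0)
        assert nb.mean == 4.0

    def test_ranking_matches_euclidean_oracle(self):
        rng = np.random.default_rng(14)
        X = _gaussian_cloud(80, seed=15)
        y = rng.normal(size=80)
        ids = [f"c{i}" for i in range(80)]
        q = rng.uniform(0, 1, X.shape[1])
        nb = nearest_neighbors(q, X, y, ids, k=10)
        dist = np.linalg.norm(X.to_numpy() - q, axis=1)
        expected = [ids[i] for i in np.argsort(dist, kind="stable")[:10]]
        assert nb.neighbors["compound_id"].tolist() == expected

    def test_statistics_over_k_neighbors(self):
        X = pd.DataFrame({"d": [0.0, 0.1, 0.9]})
        nb = nearest_neighbors(np.array([0.05]), X, [-2.0, -4.0, -9.0],
                               ["a", "b", "c"], k=2)
        assert (nb.min, nb.max, nb.mean) == (-4.0, -2.0, -3.0)

    def test_k_too_large_rejected(self):
        X = _gaussian_cloud(5, seed=16)
        with pytest.raises(ValueError):
            nearest_neighbors(X.iloc[0], X, np.zeros(5), list("abcde"), k=6)


class TestDoaReport:
    def test_empty_test_set(self):
        X = _gaussian_cloud(50, seed=17)
        model = fit_doa(X)
        empty = X.iloc[:0]
        rep = doa_report(model, empty, [], [], [], X, np.zeros(50),
                         [f"c{i}" for i in range(50)])
        assert rep.empty

    def test_in_cloud_test_set_mostly_inside(self):
        train = _gaussian_cloud(1000, seed=18)
        test = _gaussian_cloud(1000, seed=19)
        model = fit_doa(train)
        inside = inside_ellipse(model, project(model, test))
        assert inside.mean() >= 0.90

    def test_flags_and_columns(self):
        train = _gaussian_cloud(60, seed=20)
        y_train = np.random.default_rng(21).normal(-3.4, 1.9, 60)
        test = _gaussian_cloud(12, seed=22)
        y = np.linspace(-6, -1, 12)
        pred = y.copy()
        pred[0] += 5.0  # force one outlier
        out = detect_outliers(y, pred, [f"t{i}" for i in range(12)])
        rep = doa_report(fit_doa(train), test, [f"t{i}" for i in range(12)],
                         y, pred, train, y_train, [f"c{i}" for i in range(60)],
                         outliers=out)
        assert list(rep.columns) == ["compound_id", "pc1", "pc2", "inside_95",
                                     "exp_logS0", "pred_logS0", "nn_mean",
                                     "nn_min", "nn_max", "max_similarity", "flag"]
        assert rep.loc[0, "flag"] == "outlier"
        assert (rep["nn_min"] <= rep["nn_mean"]).all()
        assert (rep["nn_mean"] <= rep["nn_max"]).all()


def test_similarity_matrix_agrees_with_scalar():
    rng = np.random.default_rng(23)
    A = rng.uniform(0, 1, (4, 6))
    B = rng.uniform(0, 1, (5, 6))
    M = similarity_matrix(A, B)
    for i in range(4):
        for j in range(5):
            assert M[i, j] == pytest.approx(similarity_index(A[i], B[j]), abs=1e-12)
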