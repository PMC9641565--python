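"""Hard and fuzzy k-means, confidence scoring and treatment labeling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from roifinder.clustering import (assign_treatment_labels, confidence,
                                  flag_low_confidence, fuzzy_kmeans,
                                  _fuzzy_weights, kmeans)


def blobs(rng, n_per=20, sep=10.0, d=2):
    a = rng.normal(size=(n_per, d)) + np.array([0.0] * d)
    b = rng.normal(size=(n_per, d)) + np.array([sep] + [0.0] * (d - 1))
    X = np.vstack([a, b])
    labels = np.array([0] * n_per + [1] * n_per)
    return X, labels


class TestKMeans:
    def test_k1_center_is_centroid(self, rng):
        X = rng.normal(size=(15, 3))
        hc = kmeans(X, k=1, seed=0)
        np.testing.assert_allclose(hc.centers[0], X.mean(axis=0), atol=1e-9)
        assert hc.inertia == pytest.approx(((X - X.mean(0)) ** 2).sum())

    def test_separated_blobs_recovered(self, rng):
        X, truth = blobs(rng)
        hc = kmeans(X, k=2, seed=0)
        agree = max((hc.labels == truth).mean(),
                    (hc.labels == 1 - truth).mean())
        assert agree == 1.0

    def test_k_equals_n(self, rng):
        X = rng.normal(size=(6, 2))
        hc = kmeans(X, k=6, seed=0)
        assert hc.inertia == pytest.approx(0.0, abs=1e-12)
        assert sorted(hc.labels) == list(range(6))

    def test_n_less_than_k(self, rng):
        with pytest.raises(ValueError):
            kmeans(rng.normal(size=(2, 2)), k=3)

    def test_inertia_recomputable(self, rng):
        X = rng.normal(size=(30, 2))
        hc = kmeans(X, k=3, seed=1)
        recomputed = sum(np.sum((x - hc.centers[l]) ** 2)
                         for x, l in zip(X, hc.labels))
        assert hc.inertia == pytest.approx(recomputed)


class TestFuzzyKMeans:
    def test_point_at_center_gets_indicator_weights(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [4.0, 0.0], [4.0, 0.0],
                      [2.0, 3.0]])
        fc = fuzzy_kmeans(X, k=2, seed=0)
        # duplicated pairs are their own centers -> weight exactly 1
        for i in (0, 2):
            d = np.linalg.norm(fc.centers - X[i], axis=1)
            if d.min() == 0:
                assert fc.weights[i].max() == 1.0

    def test_equidistant_point_gets_half_weights(self):
        centers = np.array([[0.0, 0.0], [4.0, 0.0]])
        w = _fuzzy_weights(np.array([[2.0, 1.0]]), centers, m=2.0)
        np.testing.assert_allclose(w, [[0.5, 0.5]])

    def test_converged_weights_match_direct_formula(self, rng):
        X = rng.normal(size=(12, 2))
        X[6:] += 5
        fc = fuzzy_kmeans(X, k=2, seed=0, tol=1e-12)
        # brute-force recomputation of w_ij from the converged centers
        for i in range(12):
            d = np.linalg.norm(X[i] - fc.centers, axis=1)
            for j in range(2):
                w = 1.0 / np.sum((d[j] / d) ** 2)  # 2/(m-1) = 2 at m = 2
                assert fc.weights[i, j] == pytest.approx(w, abs=1e-8)

    def test_objective_non_increasing(self, rng):
        X = rng.normal(size=(40, 2))
        X[20:] += 3
        fc = fuzzy_kmeans(X, k=2, seed=0)
        hist = np.array(fc.objective_history)
        assert np.all(np.diff(hist) <= 1e-9 * max(1.0, hist[0]))

    def test_row_stochastic_weights(self, rng):
        X = rng.normal(size=(25, 3))
        fc = fuzzy_kmeans(X, k=4, seed=0)
        np.testing.assert_allclose(fc.weights.sum(axis=1), 1.0, atol=1e-9)
        assert fc.weights.min() >= 0

    def test_near_hard_limit_agrees_with_kmeans(self, rng):
        X, _ = blobs(rng)
        hard = kmeans(X, k=2, seed=0)
        fc = fuzzy_kmeans(X, k=2, m=1.05, seed=0)
        agree = max((fc.hard_labels == hard.labels).mean(),
                    (fc.hard_labels == 1 - hard.labels).mean())
        assert agree == 1.0

    def test_m_not_fuzzy_rejected(self, rng):
        with pytest.raises(ValueError, match="kmeans"):
            fuzzy_kmeans(rng.normal(size=(10, 2)), k=2, m=1.0)

    def test_confidence_grows_with_distance_from_boundary(self):
        # 1-D two-center configuration: between the centers, confidence is
        # provably monotone in the distance from the decision boundary (it
        # decays back toward 1/k far beyond a center, so the claim is local)
        centers = np.array([[-2.0], [2.0]])
        grid = np.linspace(-1.9, 1.9, 41)[:, None]
        w = _fuzzy_weights(grid, centers, m=2.0)
        conf = w.max(axis=1)
        dist = np.abs(grid[:, 0])  # boundary is the midpoint x = 0
        order = np.argsort(dist, kind="stable")
        assert np.all(np.diff(conf[order]) >= -1e-9)


class TestConfidence:
    def test_known_rows(self):
        fc = fuzzy_kmeans(np.array([[0.0], [1.0], [5.0], [6.0]]), k=2, seed=0)
        np.testing.assert_array_equal(confidence(fc),
                                      fc.weights.max(axis=1))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**16), st.integers(2, 5))
    def test_rowwise_max_oracle_and_range(self, seed, k):
        rng = np.random.default_rng(seed)
        W = rng.dirichlet(np.ones(k), size=12)
        for i, row in enumerate(W):
            assert max(row) == W[i].max()
        fc = fuzzy_kmeans(rng.normal(size=(12, 2)), k=k, seed=0)
        c = confidence(fc)
        assert np.all(c >= 1.0 / k - 1e-12) and np.all(c <= 1.0 + 1e-12)


class TestFlagging:
    def test_strictly_below_threshold(self):
        flags = flag_low_confidence(np.array([0.99, 0.5, 0.9899, 1.0]))
        np.testing.assert_array_equal(flags, [False, True, True, False])

    def test_threshold_one_flags_everything_not_exact(self):
        flags = flag_low_confidence(np.array([1.0, 0.999999]), threshold=1.0)
        np.testing.assert_array_equal(flags, [False, True])

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_invalid_threshold(self, bad):
        with pytest.raises(ValueError):
            flag_low_confidence(np.array([0.5]), threshold=bad)


class TestTreatmentLabels:
    @staticmethod
    def _table(k_values):
        n = len(k_values)
        return pd.DataFrame({
            "scan_id": ["s"] * n, "roi_id": range(n),
            "area_px": [20] * n, "eccentricity": [0.5] * n,
            "max_K": k_values,
        })

    def test_high_potassium_cluster_is_type_A(self, rng):
        from roifinder.synthetic import sample_feature_table
        from roifinder.features import feature_matrix
        from roifinder.pca import fit_pca

        table = sample_feature_table({"A": 30, "B": 30}, seed=5)
        model = fit_pca(feature_matrix(table))
        fc = fuzzy_kmeans(model.scores[:, :2], k=2, seed=0)
        mapping, predicted = assign_treatment_labels(fc, table)
        truth = table["true_label"].to_numpy()
        assert (predicted == truth).mean() >= 0.9

    def test_equal_mean_potassium_is_a_tie(self):
        fc = fuzzy_kmeans(np.array([[0.0], [0.1], [5.0], [5.1]]), k=2, seed=0)
        table = self._table([10.0, 20.0, 20.0, 10.0])
        with pytest.raises(ValueError, match="manual"):
            assign_treatment_labels(fc, table)

    def test_cluster_index_permutation_invariance(self):
        X = np.array([[0.0], [0.2], [5.0], [5.2]])
        table = self._table([50.0, 55.0, 10.0, 12.0])
        fc = fuzzy_kmeans(X, k=2, seed=0)
        _, pred = assign_treatment_labels(fc, table)
        swapped = fuzzy_kmeans(X, k=2, seed=0)
        swapped.weights = swapped.weights[:, ::-1].copy()
        swapped.centers = swapped.centers[::-1].copy()
        _, pred_swapped = assign_treatment_labels(swapped, table)
        np.testing.assert_array_equal(pred, pred_swapped)

    def test_k_not_two_rejected(self, rng):
        fc = fuzzy_kmeans(rng.normal(size=(9, 2)), k=3, seed=0)
        with pytest.raises(ValueError, match="k = 2"):
            assign_treatment_labels(fc, self._table([1.0] * 9))
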