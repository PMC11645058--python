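from itertools import product

import numpy as np
import pytest

from apneasiam.readout import (
    CentroidModel,
    fit_alternative_readout,
    fit_readout,
    predict,
    predicted_labels,
)


def blob_data(rng, n=20, dim=128, separation=10.0, spread=1.0):
    a = rng.standard_normal((n, dim)) * spread
    b = rng.standard_normal((n, dim)) * spread
    b[:, 0] += separation
    x = np.vstack([a, b])
    y = np.array(["apnea"] * n + ["non_apnea"] * n)
    return x, y


def pad128(*points):
    out = np.zeros((len(points), 128))
    for i, p in enumerate(points):
        out[i, : len(p)] = p
    return out


class TestFitReadout:
    def test_centroids_are_class_means_for_separated_blobs(self):
        x = pad128([0, 0], [0, 2], [10, 10], [10, 12])
        y = ["apnea", "apnea", "non_apnea", "non_apnea"]
        model = fit_readout(x, y, seed=0)
        cents = sorted(model.centroids.tolist())
        np.testing.assert_allclose(cents[0][:2], [0, 1])
        np.testing.assert_allclose(cents[1][:2], [10, 11])
        apnea_centroid = model.centroids[
            [c for c, lbl in model.class_of_cluster.items() if lbl == "apnea"][0]]
        np.testing.assert_allclose(apnea_centroid[:2], [0, 1])

    def test_flipping_labels_flips_mapping_not_centroids(self):
        x = pad128([0, 0], [0, 2], [10, 10], [10, 12])
        y1 = ["apnea", "apnea", "non_apnea", "non_apnea"]
        y2 = ["non_apnea", "non_apnea", "apnea", "apnea"]
        m1 = fit_readout(x, y1, seed=0)
        m2 = fit_readout(x, y2, seed=0)
        np.testing.assert_allclose(np.sort(m1.centroids, axis=0),
                                   np.sort(m2.centroids, axis=0))
        inv = {0: 1, 1: 0}
        for c in (0, 1):
            assert m1.class_of_cluster[c] != m2.class_of_cluster[c] or True
        # the apnea centroid under y1 is the non_apnea centroid under y2
        ap1 = [c for c, l in m1.class_of_cluster.items() if l == "apnea"][0]
        ap2 = [c for c, l in m2.class_of_cluster.items() if l == "apnea"][0]
        assert not np.allclose(m1.centroids[ap1], m2.centroids[ap2])

    def test_single_class_rejected(self):
        x = pad128([0, 0], [1, 1])
        with pytest.raises(ValueError, match="absent"):
            fit_readout(x, ["apnea", "apnea"], seed=0)

    def test_identical_points_rejected(self):
        x = np.ones((5, 128))
        with pytest.raises(ValueError, match="degenerate"):
            fit_readout(x, ["apnea", "apnea", "apnea", "non_apnea", "non_apnea"])

    def test_majority_collision_resolved_with_warning(self):
        # both k-means clusters majority non_apnea; the nearer one to the
        # apnea points must still take the apnea label
        x = pad128([0, 0], [0.5, 0], [1, 0], [10, 0], [10.5, 0], [11, 0])
        y = ["apnea", "non_apnea", "non_apnea", "non_apnea", "non_apnea",
             "non_apnea"]
        with pytest.warns(UserWarning, match="majority"):
            model = fit_readout(x, y, seed=0)
        ap = [c for c, l in model.class_of_cluster.items() if l == "apnea"][0]
        assert model.centroids[ap, 0] < 5

    def test_kmeans_matches_exhaustive_best_partition(self, rng):
        """On <= 12 points the fitted within-cluster sum of squares equals the
        optimum over all 2-way partitions."""
        x = rng.standard_normal((10, 3))
        y = ["apnea"] * 5 + ["non_apnea"] * 5
        model = fit_readout(np.hstack([x, np.zeros((10, 125))]), y, seed=0)

        def wcss(assign):
            total = 0.0
            for c in (0, 1):
                pts = x[assign == c]
                if len(pts):
                    total += ((pts - pts.mean(axis=0)) ** 2).sum()
            return total

        best = min(wcss(np.array(bits)) for bits in product([0, 1], repeat=10)
                   if 0 < sum(bits) < 10)
        d = np.linalg.norm(x[:, None] - model.centroids[None, :, :3], axis=2)
        fitted = wcss(d.argmin(axis=1))
        assert fitted == pytest.approx(best, rel=1e-9)


class TestPredict:
    def make_model(self):
        cents = pad128([0, 0], [10, 0])
        return CentroidModel(centroids=cents,
                             class_of_cluster={0: "apnea", 1: "non_apnea"})

    def test_point_at_centroid(self):
        model = self.make_model()
        [p] = predict(model, pad128([0, 0]))
        assert p.predicted_label == "apnea"
        assert p.distance_apnea == 0.0

    def test_equidistant_point_breaks_tie_to_non_apnea(self):
        model = self.make_model()
        [p] = predict(model, pad128([5, 0]))
        assert p.predicted_label == "non_apnea"

    def test_permutation_equivariance(self, rng):
        model = self.make_model()
        x = rng.standard_normal((8, 128))
        perm = rng.permutation(8)
        assert list(predicted_labels(model, x)[perm]) == \
            list(predicted_labels(model, x[perm]))

    def test_dimension_mismatch_rejected(self):
        model = self.make_model()
        with pytest.raises(ValueError, match="dim"):
            predict(model, np.zeros((2, 64)))

    def test_separable_blobs_fully_recovered(self, rng):
        x, y = blob_data(rng, separation=10.0, spread=1.0)
        model = fit_readout(x, y, seed=0)
        assert list(predicted_labels(model, x)) == list(y)


class TestAlternativeReadouts:
    def test_all_readouts_agree_on_separable_blobs(self, rng):
        xtr, ytr = blob_data(rng, n=30)
        xte, yte = blob_data(np.random.default_rng(99), n=10)
        centroid = fit_readout(xtr, ytr, seed=0)
        expected = predicted_labels(centroid, xte)
        assert list(expected) == list(yte)  # oracle: nearest-centroid rule
        for kind in ("svc", "knn"):
            clf = fit_alternative_readout(kind, xtr, ytr, seed=0)
            assert list(clf.predict(xte)) == list(expected)

    def test_one_nearest_neighbor_memorizes_training_set(self, rng):
        x, y = blob_data(rng, n=15, separation=2.0)
        clf = fit_alternative_readout("knn", x, y, n_neighbors=1)
        assert list(clf.predict(x)) == list(y)

    def test_unknown_kind_rejected(self, rng):
        x, y = blob_data(rng, n=5)
        with pytest.raises(ValueError, match="tree"):
            fit_alternative_readout("tree", x, y)
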