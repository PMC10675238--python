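import numpy as np
import pytest

from fermsense import adpc


def brute_density(dist, dc):
    n = dist.shape[0]
    rho = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j:
                rho[i] += np.exp(-((dist[i, j] / dc) ** 2))
    return rho


def brute_delta(dist, rho):
    n = len(rho)
    delta = np.zeros(n)
    for i in range(n):
        higher = [j for j in range(n)
                  if rho[j] > rho[i] or (rho[j] == rho[i] and j < i)]
        delta[i] = min(dist[i, j] for j in higher) if higher else dist[i].max()
    return delta


class TestLocalDensity:
    def test_single_point_zero(self):
        assert adpc.local_density(np.zeros((1, 1)), 1.0)[0] == 0.0

    def test_two_points_at_cutoff(self):
        dist = np.array([[0.0, 2.0], [2.0, 0.0]])
        rho = adpc.local_density(dist, 2.0)
        np.testing.assert_allclose(rho, np.exp(-1.0))

    def test_three_coincident(self):
        rho = adpc.local_density(np.zeros((3, 3)), 1.0)
        np.testing.assert_allclose(rho, 2.0)

    def test_requires_positive_cutoff(self):
        with pytest.raises(ValueError):
            adpc.local_density(np.zeros((2, 2)), 0.0)

    def test_matches_double_loop_oracle(self, rng):
        X = rng.normal(size=(40, 3))
        dist = adpc.pairwise_distances(X)
        dc = adpc.truncation_distance(dist)
        np.testing.assert_allclose(adpc.local_density(dist, dc),
                                   brute_density(dist, dc), atol=1e-12)


class TestRelativeDistance:
    def test_collinear_example(self):
        # points at 0, 1, 5 with densities 1, 3, 2
        X = np.array([[0.0], [1.0], [5.0]])
        dist = adpc.pairwise_distances(X)
        delta = adpc.relative_distance(dist, np.array([1.0, 3.0, 2.0]))
        np.testing.assert_allclose(delta, [1.0, 4.0, 4.0])

    def test_two_points_densest_gets_max(self):
        dist = np.array([[0.0, 3.0], [3.0, 0.0]])
        delta = adpc.relative_distance(dist, np.array([1.0, 2.0]))
        assert delta[1] == 3.0 and delta[0] == 3.0

    def test_non_densest_bounded_by_row_max(self, rng):
        X = rng.normal(size=(30, 2))
        dist = adpc.pairwise_distances(X)
        rho = adpc.local_density(dist, adpc.truncation_distance(dist))
        delta = adpc.relative_distance(dist, rho)
        top = np.lexsort((np.arange(30), -rho))[0]
        for i in range(30):
            if i != top:
                assert delta[i] <= dist[i].max() + 1e-12

    def test_matches_brute_force(self, rng):
        X = rng.normal(size=(50, 2))
        dist = adpc.pairwise_distances(X)
        rho = adpc.local_density(dist, adpc.truncation_distance(dist))
        np.testing.assert_allclose(adpc.relative_distance(dist, rho),
                                   brute_delta(dist, rho), atol=1e-12)


class TestDecisionParameters:
    def test_rescaled_delta_at_ten_gives_D_equal_rho(self):
        # the point holding the largest delta gets delta_tilde = 10, lg = 1
        rho = np.array([4.0, 1.0, 1.0])
        delta = np.array([9.0, 2.0, 1.0])
        prof = adpc.decision_parameters(rho, delta)
        assert prof.D[0] == pytest.approx(4.0)

    def test_drop_statistic_hand_example(self):
        # first four points share delta_tilde = 10 (lg = 1), the last gets
        # delta_tilde = 1 (lg = 0), so gamma = (10, 9.5, 2, 1.9, 0) and
        # gamma*_3 = (9.5 - 2) / (2 - 1.9) = 75
        prof = adpc.decision_parameters(
            np.array([10.0, 9.5, 2.0, 1.9, 1.8]),
            np.array([100.0, 100.0, 100.0, 100.0, 0.001]),
        )
        assert prof.gamma_star[2] == pytest.approx(75.0, rel=1e-9)

    def test_constant_D_degenerate(self):
        prof = adpc.decision_parameters(np.ones(5), np.ones(5))
        # delta rescaling is flat -> D identically 0; gamma* floored, all equal
        assert np.allclose(prof.D, 0.0)
        inner = prof.gamma_star[1:-1]
        assert np.allclose(inner, inner[0])

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            adpc.decision_parameters(np.ones(2), np.ones(2))


def _blobs(rng, centers, n_each=100, sd=0.5):
    X = np.vstack([np.asarray(c) + rng.normal(0, sd, size=(n_each, len(c)))
                   for c in centers])
    labels = np.repeat(np.arange(len(centers)), n_each)
    return X, labels


class TestCenterSelection:
    def test_two_separated_blobs_recover_k2(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X, _ = _blobs(rng, [[0, 0], [10, 0]])
            part, _ = adpc.cluster(X)
            hits += part.k == 2
        assert hits >= 18

    def test_k_max_caps_center_count(self, rng):
        X, _ = _blobs(rng, [[0, 0], [10, 0], [5, 10]])
        part, prof = adpc.cluster(X, k_max=2)
        assert part.k <= 2

    def test_single_blob_often_one_cluster(self):
        # a single tight blob should not shatter into many clusters
        ks = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X, _ = _blobs(rng, [[0, 0]], sd=0.1)
            part, _ = adpc.cluster(X)
            ks.append(part.k)
        assert np.median(ks) <= 3


class TestAssignment:
    def test_labels_conserve_and_clusters_nonempty(self, rng):
        X, _ = _blobs(rng, [[0, 0], [8, 8]])
        part, _ = adpc.cluster(X)
        assert len(part.labels) == len(X)
        assert set(part.labels) == set(range(1, part.k + 1))
        for lbl in range(1, part.k + 1):
            assert (part.labels == lbl).sum() > 0

    def test_point_coincident_with_center_shares_label(self, rng):
        X, _ = _blobs(rng, [[0, 0], [10, 0]])
        part, prof = adpc.cluster(X)
        c = part.center_indices[0]
        X2 = np.vstack([X, X[c]])          # duplicate a center
        part2, _ = adpc.cluster(X2)
        c2 = [i for i in part2.center_indices
              if np.allclose(X2[i], X[c])]
        if c2:  # duplicated point must share its center's cluster
            assert part2.labels[-1] == part2.labels[c2[0]]

    def test_merge_small_clusters(self, rng):
        X, _ = _blobs(rng, [[0, 0], [10, 0]], n_each=50)
        part, _ = adpc.cluster(X)
        merged = adpc.merge_small_clusters(X, part, min_size=60)
        sizes = np.bincount(merged.labels)[1:]
        assert (sizes >= 60).all() or merged.k == 1
        assert merged.labels.shape == part.labels.shape


def test_partition_and_profile_export(rng):
    X, _ = _blobs(rng, [[0, 0], [10, 0]], n_each=40)
    part, prof = adpc.cluster(X)
    df = part.to_frame()
    assert list(df.columns) == ["row_index", "label"] and len(df) == 80
    import json

    diag = json.loads(json.dumps(prof.diagnostics()))
    assert len(diag["rho"]) == 80 and diag["dist_c"] > 0
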