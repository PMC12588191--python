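import numpy as np
import pytest

from preictal.cluster import (
    ClusterResult,
    calinski_harabasz,
    davies_bouldin,
    dbscan_baseline,
    elbow_from_curve,
    kmeans,
    method_comparison,
    noise_filter,
    select_k,
    silhouette,
    ward_baseline,
)

TWO_CLUSTERS_1D = np.array([[0.0], [1.0], [10.0], [11.0]])
TWO_CLUSTERS_LABELS = np.array([0, 0, 1, 1])


# ------------------------------------------------------------- oracles

def silhouette_oracle(E, labels):
    E = np.asarray(E, float)
    n = len(E)
    d = np.linalg.norm(E[:, None] - E[None, :], axis=-1)
    scores = []
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            scores.append(0.0)
            continue
        a = d[i][own].sum() / (n_own - 1)
        b = min(
            d[i][labels == c].mean() for c in set(labels) if c != labels[i]
        )
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


def davies_bouldin_oracle(E, labels):
    E = np.asarray(E, float)
    cs = sorted(set(labels))
    cents = np.array([E[labels == c].mean(axis=0) for c in cs])
    S = np.array(
        [np.linalg.norm(E[labels == c] - cents[i], axis=1).mean()
         for i, c in enumerate(cs)]
    )
    total = 0.0
    for i in range(len(cs)):
        worst = max(
            (S[i] + S[j]) / np.linalg.norm(cents[i] - cents[j])
            for j in range(len(cs)) if j != i
        )
        total += worst
    return total / len(cs)


def calinski_harabasz_oracle(E, labels):
    E = np.asarray(E, float)
    cs = sorted(set(labels))
    n, k = len(E), len(cs)
    grand = E.mean(axis=0)
    B = sum(
        (labels == c).sum() * np.linalg.norm(E[labels == c].mean(axis=0) - grand) ** 2
        for c in cs
    )
    W = sum(
        np.linalg.norm(E[labels == c] - E[labels == c].mean(axis=0)) ** 2
        for c in cs
    )
    return (B / (k - 1)) / (W / (n - k))


@pytest.fixture(scope="module")
def random_labelled_points():
    rng = np.random.default_rng(0)
    E = rng.standard_normal((50, 2))
    labels = rng.integers(0, 3, size=50)
    return E, labels


# ------------------------------------------------------------- K-Means

class TestKMeans:
    def test_k_equals_n_gives_zero_inertia(self):
        rng = np.random.default_rng(1)
        E = rng.standard_normal((6, 2))
        result = kmeans(E, k=6, seed=0)
        assert result.inertia == pytest.approx(0.0, abs=1e-12)
        assert len(set(result.labels.tolist())) == 6

    def test_two_pairs_partition_enumeration(self):
        # optimal 2-partition of {0,1,10,11} is {0,1}|{10,11}: inertia 1.0
        result = kmeans(TWO_CLUSTERS_1D, k=2, seed=0)
        assert sorted(result.centroids.ravel().tolist()) == [0.5, 10.5]
        assert result.inertia == pytest.approx(1.0)
        assert result.labels[0] == result.labels[1] != result.labels[2]

    def test_same_seed_same_labels(self):
        rng = np.random.default_rng(2)
        E = rng.standard_normal((100, 2))
        assert np.array_equal(
            kmeans(E, 4, seed=9).labels, kmeans(E, 4, seed=9).labels
        )

    def test_k_beyond_n_rejected(self):
        with pytest.raises(ValueError):
            kmeans(TWO_CLUSTERS_1D, k=5)

    def test_multistart_never_worse_than_single_start(self):
        rng = np.random.default_rng(12)
        E = rng.standard_normal((200, 2))
        multi = kmeans(E, 5, seed=0, n_init=10).inertia
        single = kmeans(E, 5, seed=0, n_init=1).inertia
        assert multi <= single + 1e-9


# ------------------------------------------------------------- validity metrics

class TestValidityMetrics:
    def test_silhouette_hand_computed_value(self):
        assert silhouette(TWO_CLUSTERS_1D, TWO_CLUSTERS_LABELS) == pytest.approx(
            0.8997, abs=5e-5
        )

    def test_silhouette_coincident_clusters_near_zero(self):
        E = np.array([[0.0, 0.0]] * 6)
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert abs(silhouette(E, labels)) < 1e-12

    def test_silhouette_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette(TWO_CLUSTERS_1D, np.zeros(4, dtype=int))

    def test_davies_bouldin_hand_computed_value(self):
        assert davies_bouldin(TWO_CLUSTERS_1D, TWO_CLUSTERS_LABELS) == pytest.approx(
            0.1
        )

    def test_davies_bouldin_coincident_centroids_rejected(self):
        E = np.array([[0.0], [1.0], [0.0], [1.0]])
        with pytest.raises(ValueError, match="coincident"):
            davies_bouldin(E, np.array([0, 0, 1, 1]))

    def test_calinski_harabasz_hand_computed_value(self):
        assert calinski_harabasz(
            TWO_CLUSTERS_1D, TWO_CLUSTERS_LABELS
        ) == pytest.approx(200.0)

    def test_calinski_harabasz_zero_within_scatter_is_inf(self):
        E = np.array([[0.0], [0.0], [5.0], [5.0]])
        assert calinski_harabasz(E, np.array([0, 0, 1, 1])) == np.inf

    def test_all_metrics_match_bruteforce_oracles(self, random_labelled_points):
        E, labels = random_labelled_points
        assert silhouette(E, labels) == pytest.approx(
            silhouette_oracle(E, labels), rel=1e-8
        )
        assert davies_bouldin(E, labels) == pytest.approx(
            davies_bouldin_oracle(E, labels), rel=1e-8
        )
        assert calinski_harabasz(E, labels) == pytest.approx(
            calinski_harabasz_oracle(E, labels), rel=1e-8
        )


# ------------------------------------------------------------- k selection

class TestSelectK:
    def test_elbow_from_prescribed_curve(self):
        elbow, _ = elbow_from_curve([1, 2, 3, 4, 5], [100, 20, 10, 8, 7])
        assert elbow == 2

    def test_elbow_tie_resolves_to_smallest_k(self):
        # symmetric curvature at k=2 and k=3
        elbow, curv = elbow_from_curve([1, 2, 3, 4], [30, 10, 10, 10])
        assert curv[2] == curv[3] == pytest.approx(20.0) or elbow == 2
        assert elbow == 2

    def test_increasing_inertia_curve_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            elbow_from_curve([1, 2, 3, 4], [10, 20, 30, 40])

    def test_recovers_four_planted_blobs(self):
        rng = np.random.default_rng(3)
        centers = np.array([[0, 0], [10, 0], [0, 10], [10, 10]], float)
        E = np.vstack([c + 0.5 * rng.standard_normal((80, 2)) for c in centers])
        k, elbow_k, sil_k, diag = select_k(E, seed=0)
        assert k == 4 and sil_k == 4
        assert diag["silhouette"][4] == max(diag["silhouette"].values())

    def test_planted_blob_recovery_across_replicates(self):
        """The silhouette scan recovers the planted count in >=95 % of runs."""
        hits = 0
        centers = np.array([[0, 0], [8, 0], [0, 8], [8, 8]], float)
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            E = np.vstack(
                [c + 0.6 * rng.standard_normal((60, 2)) for c in centers]
            )
            k, _, _, _ = select_k(E, seed=seed)
            hits += k == 4
        assert hits >= 19


# ------------------------------------------------------------- baselines

class TestBaselines:
    def test_dbscan_finds_two_blobs_with_little_noise(self):
        rng = np.random.default_rng(4)
        E = np.vstack(
            [c + 0.3 * rng.standard_normal((100, 2)) for c in ((0, 0), (10, 10))]
        )
        result = dbscan_baseline(E)
        assert result.k == 2
        assert (result.labels == -1).mean() < 0.05

    def test_dbscan_all_noise_rejected(self):
        # no point can ever reach min_samples neighbours
        E = np.column_stack([np.linspace(0, 1000, 12), np.zeros(12)])
        with pytest.raises(ValueError, match="noise"):
            dbscan_baseline(E, min_samples=13)

    def test_ward_partitions_two_pairs(self):
        result = ward_baseline(TWO_CLUSTERS_1D, k=2)
        assert result.labels[0] == result.labels[1] != result.labels[2]
        assert result.labels[2] == result.labels[3]
        assert result.inertia == pytest.approx(1.0)

    def test_method_comparison_lists_three_methods(self):
        rng = np.random.default_rng(5)
        E = np.vstack(
            [c + 0.3 * rng.standard_normal((60, 2)) for c in ((0, 0), (8, 8))]
        )
        table = method_comparison(E, k=2, seed=0)
        assert table["method"].tolist() == ["kmeans", "dbscan", "ward"]
        assert {"silhouette", "davies_bouldin", "calinski_harabasz"} <= set(
            table.columns
        )


# ------------------------------------------------------------- noise filter

def _result_with_sizes(sizes, rng):
    points, labels = [], []
    for c, size in enumerate(sizes):
        points.append(np.array([10.0 * c, 0.0]) + 0.2 * rng.standard_normal((size, 2)))
        labels.extend([c] * size)
    E = np.vstack(points)
    labels = np.array(labels)
    cents = np.array([E[labels == c].mean(axis=0) for c in range(len(sizes))])
    inertia = float(sum(((E[labels == c] - cents[c]) ** 2).sum() for c in range(len(sizes))))
    return E, ClusterResult(labels, len(sizes), cents, inertia, "kmeans", 0)


class TestNoiseFilter:
    def test_undersized_cluster_relabelled_not_dropped(self):
        rng = np.random.default_rng(6)
        E, result = _result_with_sizes([150, 80, 19], rng)
        filtered, removed, pre, post = noise_filter(E, result, min_size=20)
        assert filtered.k == 2
        assert removed.sum() == 19
        assert (filtered.labels >= 0).sum() == 230
        assert len(filtered.labels) == 249  # nothing silently dropped
        assert pre.stage == "pre_filter" and post.stage == "post_filter"

    def test_all_clusters_large_is_identity(self):
        rng = np.random.default_rng(7)
        E, result = _result_with_sizes([40, 30], rng)
        filtered, removed, pre, post = noise_filter(E, result, min_size=20)
        assert np.array_equal(filtered.labels, result.labels)
        assert removed.sum() == 0
        assert pre.silhouette == post.silhouette

    def test_exactly_min_size_survives(self):
        rng = np.random.default_rng(8)
        E, result = _result_with_sizes([40, 20], rng)
        filtered, removed, _, _ = noise_filter(E, result, min_size=20)
        assert filtered.k == 2 and removed.sum() == 0

    def test_every_cluster_undersized_rejected(self):
        rng = np.random.default_rng(9)
        E, result = _result_with_sizes([10, 12], rng)
        with pytest.raises(ValueError, match="fewer than"):
            noise_filter(E, result, min_size=20)

    def test_retained_plus_removed_is_total(self):
        rng = np.random.default_rng(10)
        E, result = _result_with_sizes([33, 21, 5, 3], rng)
        filtered, removed, _, _ = noise_filter(E, result, min_size=20)
        assert (filtered.labels >= 0).sum() + removed.sum() == len(E)
        sizes = filtered.cluster_sizes()
        assert all(s >= 20 for c, s in sizes.items() if c >= 0)
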