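"""k-means, validity indices, elbow and architecture selection."""

import numpy as np
import pytest

import sleeppi as sp
from sleeppi.clustering import CH_PERFECT, ClusterSolution
from sleeppi.errors import ConfigurationError


# ---------------------------------------------------------------------------
# Brute-force reference implementations (test-side oracles)
# ---------------------------------------------------------------------------


def ch_bruteforce(Z, labels):
    Z = np.asarray(Z, float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    n, k = len(Z), len(uniq)
    grand = Z.mean(axis=0)
    B = W = 0.0
    for u in uniq:
        sub = Z[labels == u]
        mu = sub.mean(axis=0)
        B += len(sub) * float(((mu - grand) ** 2).sum())
        W += float(((sub - mu) ** 2).sum())
    return (B / (k - 1)) / (W / (n - k))


def silhouette_bruteforce(Z, labels):
    Z = np.asarray(Z, float)
    labels = np.asarray(labels)
    n = len(Z)
    dist = np.sqrt(((Z[:, None, :] - Z[None, :, :]) ** 2).sum(axis=2))
    scores = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        if own.sum() == 1:
            scores[i] = 0.0
            continue
        a = dist[i, own].sum() / (own.sum() - 1)
        b = min(
            dist[i, labels == u].mean() for u in np.unique(labels) if u != labels[i]
        )
        scores[i] = (b - a) / max(a, b)
    return scores.mean()


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------


def test_kmeans_k1_closed_form():
    rng = np.random.default_rng(0)
    Z = rng.normal(size=(50, 3))
    sol = sp.fit_kmeans(Z, 1, seed=0)
    assert np.allclose(sol.centroids[0], Z.mean(axis=0))
    assert sol.wcss == pytest.approx(float(((Z - Z.mean(0)) ** 2).sum()))


def test_kmeans_two_blob_hand_case():
    Z = np.array([[0.0], [1.0], [10.0], [11.0]])
    sol = sp.fit_kmeans(Z, 2, seed=0)
    assert sorted(sol.centroids.ravel()) == [0.5, 10.5]
    assert sol.wcss == pytest.approx(1.0)
    assert sol.labels[0] == sol.labels[1] != sol.labels[2] == sol.labels[3]


def test_kmeans_duplicated_points_double_wcss():
    rng = np.random.default_rng(1)
    Z = rng.normal(size=(40, 2)) + np.repeat([[0, 0], [8, 8]], 20, axis=0)
    sol = sp.fit_kmeans(Z, 2, seed=0)
    doubled = sp.fit_kmeans(np.vstack([Z, Z]), 2, seed=0)
    assert doubled.wcss == pytest.approx(2 * sol.wcss, rel=1e-9)
    assert np.allclose(np.sort(doubled.centroids, 0), np.sort(sol.centroids, 0))


def test_kmeans_input_validation():
    with pytest.raises(ConfigurationError):
        sp.fit_kmeans(np.zeros((3, 2)), 4)
    with pytest.raises(ConfigurationError):
        sp.fit_kmeans(np.array([[np.inf, 0.0]]), 1)


# ---------------------------------------------------------------------------
# Validity indices
# ---------------------------------------------------------------------------


def test_ch_hand_case():
    Z = np.array([[0.0], [1.0], [10.0], [11.0]])
    labels = np.array([0, 0, 1, 1])
    assert sp.calinski_harabasz(Z, labels) == pytest.approx(200.0)


def test_ch_label_permutation_invariance():
    rng = np.random.default_rng(2)
    Z = rng.normal(size=(60, 3))
    labels = rng.integers(0, 3, 60)
    relabelled = (labels + 1) % 3
    assert sp.calinski_harabasz(Z, labels) == pytest.approx(
        sp.calinski_harabasz(Z, relabelled)
    )


def test_ch_perfect_separation_sentinel():
    Z = np.repeat([[0.0], [5.0]], 5, axis=0)
    labels = np.repeat([0, 1], 5)
    assert sp.calinski_harabasz(Z, labels) == CH_PERFECT


def test_ch_null_expectation_near_one():
    """Random labels on isotropic noise give CH about 1 on average."""
    rng = np.random.default_rng(3)
    values = []
    for _ in range(30):
        Z = rng.normal(size=(150, 4))
        labels = rng.integers(0, 3, 150)
        values.append(sp.calinski_harabasz(Z, labels))
    assert 0.75 < np.mean(values) < 1.3


def test_silhouette_hand_case():
    Z = np.array([[0.0], [1.0], [10.0], [11.0]])
    labels = np.array([0, 0, 1, 1])
    assert sp.silhouette(Z, labels) == pytest.approx(0.89975, abs=1e-5)


def test_singleton_clusters_score_zero_silhouette():
    Z = np.array([[0.0], [10.0]])
    assert sp.silhouette(Z, np.array([0, 1])) == 0.0


def test_indices_match_bruteforce_on_random_instances():
    rng = np.random.default_rng(4)
    for trial in range(5):
        n = int(rng.integers(30, 120))
        Z = rng.normal(size=(n, int(rng.integers(2, 5))))
        labels = rng.integers(0, 3, n)
        if len(np.unique(labels)) < 2:
            continue
        assert sp.calinski_harabasz(Z, labels) == pytest.approx(
            ch_bruteforce(Z, labels), abs=1e-9, rel=1e-9
        )
        assert sp.silhouette(Z, labels) == pytest.approx(
            silhouette_bruteforce(Z, labels), abs=1e-9
        )


def test_indices_reject_degenerate_inputs():
    Z = np.zeros((5, 2))
    with pytest.raises(ConfigurationError):
        sp.calinski_harabasz(Z, np.zeros(5, dtype=int))
    with pytest.raises(ConfigurationError):
        sp.silhouette(Z, np.zeros(5, dtype=int))


# ---------------------------------------------------------------------------
# Elbow selection
# ---------------------------------------------------------------------------


def test_elbow_hand_example():
    res = sp.elbow_select({1: 100.0, 2: 20.0, 3: 18.0, 4: 17.0, 5: 16.0})
    assert res.k == 2 and not res.no_elbow


def test_elbow_flags_linear_curves():
    with pytest.warns(UserWarning, match="no clear elbow"):
        res = sp.elbow_select({k: 100.0 - 10 * k for k in range(1, 8)})
    assert res.no_elbow


def test_elbow_input_validation():
    with pytest.raises(ConfigurationError):
        sp.elbow_select({1: 3.0, 2: 2.0})
    with pytest.raises(ConfigurationError):
        sp.elbow_select({1: 3.0, 2: 2.0, 4: 1.0})


def test_elbow_recovers_three_separated_blobs():
    rng = np.random.default_rng(5)
    centers = np.array([[0, 0], [12, 0], [0, 12]])
    Z = np.vstack([c + rng.normal(size=(80, 2)) for c in centers])
    curve = sp.wcss_curve(Z, range(1, 11), restarts=5, seed=0)
    assert sp.elbow_select(curve).k == 3


def test_wcss_curve_is_nonincreasing(medium_features):
    Z = medium_features["train"].X[:400, :10]
    curve = sp.wcss_curve(Z, range(1, 9), restarts=3, seed=0)
    values = [curve[k] for k in sorted(curve)]
    assert all(b <= a + 1e-9 for a, b in zip(values, values[1:]))


# ---------------------------------------------------------------------------
# Architecture selection
# ---------------------------------------------------------------------------


def _grid(rows):
    import pandas as pd

    return pd.DataFrame(rows, columns=["feature_set", "k", "ch_index", "silhouette"])


def test_select_architecture_picks_dominating_candidate():
    rows = []
    for k in (2, 3, 4):
        rows += [
            ("raw", k, 10.0, 0.1),
            ("pca", k, 50.0, 0.3),
            ("dae_J=2", k, 90.0, 0.6),
        ]
    winner, ranking = sp.select_architecture(_grid(rows))
    assert winner == "dae_J=2"
    assert list(ranking["feature_set"]) == ["dae_J=2", "pca", "raw"]


def test_select_architecture_single_candidate():
    rows = [("only", k, 1.0, 0.5) for k in (2, 3, 4)]
    assert sp.select_architecture(_grid(rows))[0] == "only"


def test_select_architecture_mixed_dominance_matches_exhaustive_ranking():
    """Two candidates that trade wins are ranked by the normalised mean."""
    rows = []
    for k, (ch_a, sil_a, ch_b, sil_b) in zip(
        (2, 3, 4), [(90, 0.2, 30, 0.6), (80, 0.25, 40, 0.5), (85, 0.3, 35, 0.55)]
    ):
        rows += [("a", k, ch_a, sil_a), ("b", k, ch_b, sil_b)]
    winner, ranking = sp.select_architecture(_grid(rows))
    # hand ranking: per (k, metric) min-max normalisation gives each candidate
    # 1.0 on its winning metric and 0.0 on the other, so both average 0.5 and
    # the stable order keeps the first-listed candidate on top
    assert ranking["score"].tolist() == pytest.approx([0.5, 0.5])
    assert winner == "a"


def test_select_architecture_rejects_missing_cells():
    rows = [("a", 2, 1.0, 0.5), ("a", 3, 1.0, 0.5)]
    with pytest.raises(ConfigurationError):
        sp.select_architecture(_grid(rows))


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------


def test_assign_consistent_with_fit(medium_features):
    Z = medium_features["train"].X[:300, :5]
    sol = sp.fit_kmeans(Z, 3, seed=0)
    assert np.array_equal(sp.assign(sol, Z), sol.labels)


def test_assign_tie_breaks_to_lowest_index():
    sol = ClusterSolution(
        k=2, centroids=np.array([[0.0], [10.0]]), labels=np.array([0, 1]), wcss=0.0
    )
    assert sp.assign(sol, np.array([[5.0]]))[0] == 0  # equidistant
    assert sp.assign(sol, np.array([[4.0]]))[0] == 0
    assert sp.assign(sol, np.array([[8.0]]))[0] == 1
    with pytest.raises(ConfigurationError):
        sp.assign(sol, np.zeros((2, 3)))
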