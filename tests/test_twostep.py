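import numpy as np
import pytest

from alsclust.twostep import (CFTreeParams, ClusteringError, PreCluster,
                              agglomerate, assign_clusters, bic,
                              build_cf_tree, cluster_scores, mean_silhouette,
                              select_cluster_count)

from conftest import (naive_centroid_agglomeration, naive_mean_silhouette,
                      partition_sets)


def _embed(points_1d):
    """1-D points embedded in 15-D (remaining coordinates zero)."""
    X = np.zeros((len(points_1d), 15))
    X[:, 0] = points_1d
    return X


def _two_blobs(n_per=10, shift=3.0, d=15, seed=0, noise=1.0):
    """Two spherical Gaussian blobs offset by *shift* noise-SDs per dimension."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, noise, (n_per, d))
    b = rng.normal(shift * noise, noise, (n_per, d))
    return np.vstack([a, b]), np.repeat([0, 1], n_per)


# ------------------------------------------------------------------ CF-tree

def test_bypass_tree_yields_singletons():
    X = np.random.default_rng(0).normal(size=(20, 15))
    pcs = build_cf_tree(X, CFTreeParams(bypass_tree=True))
    assert len(pcs) == 20
    assert all(pc.n == 1 for pc in pcs)
    assert sorted(i for pc in pcs for i in pc.member_ids) == list(range(20))


def test_cf_tree_does_not_mix_well_separated_clouds():
    X, truth = _two_blobs(n_per=10, shift=20.0, seed=1)
    params = CFTreeParams(bypass_tree=False, max_leaf_entries=2,
                          branching_factor=2, max_depth=2, initial_threshold=5.0)
    pcs = build_cf_tree(X, params)
    assert 2 <= len(pcs) <= 10
    for pc in pcs:
        clouds = {truth[i] for i in pc.member_ids}
        assert len(clouds) == 1, "pre-cluster mixes the two clouds"
    assert sorted(i for pc in pcs for i in pc.member_ids) == list(range(len(X)))


def test_cf_tree_absorbs_duplicate_points():
    X = np.tile(np.arange(5.0)[:, None], (3, 15))  # each point three times
    params = CFTreeParams(bypass_tree=False, initial_threshold=0.1)
    pcs = build_cf_tree(X, params)
    assert len(pcs) == 5
    assert sorted(pc.n for pc in pcs) == [3, 3, 3, 3, 3]


def test_cf_tree_rejects_nan_and_tiny_input():
    with pytest.raises(ClusteringError):
        build_cf_tree(np.full((3, 2), np.nan))
    with pytest.raises(ClusteringError):
        build_cf_tree(np.zeros((1, 15)))


def test_sufficient_statistics_exactness():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(40, 15))
    pcs = build_cf_tree(X, CFTreeParams(bypass_tree=False, initial_threshold=1.0,
                                        max_leaf_entries=4, branching_factor=4))
    for pc in pcs:
        members = X[pc.member_ids]
        np.testing.assert_allclose(pc.linear_sum, members.sum(axis=0), atol=1e-9)
        np.testing.assert_allclose(pc.square_sum, (members ** 2).sum(axis=0), atol=1e-9)
    merged = pcs[0].merged(pcs[1])
    both = X[pcs[0].member_ids + pcs[1].member_ids]
    np.testing.assert_allclose(merged.linear_sum, both.sum(axis=0), atol=1e-9)
    np.testing.assert_allclose(merged.square_sum, (both ** 2).sum(axis=0), atol=1e-9)


# ------------------------------------------------------------- agglomeration

def test_first_merge_is_nearest_pair():
    X = _embed([0.0, 1.0, 10.0])
    dend = agglomerate(build_cf_tree(X), X)
    i, j, d = dend.merges[0]
    assert {i, j} == {0, 1}
    assert d == pytest.approx(1.0)


def test_duplicate_preclusters_merge_at_distance_zero_first():
    X = _embed([5.0, 5.0, 1.0, 9.0])
    dend = agglomerate(build_cf_tree(X), X)
    i, j, d = dend.merges[0]
    assert {i, j} == {0, 1}
    assert d == 0.0


def test_merge_sequence_equals_naive_oracle():
    rng = np.random.default_rng(11)
    X = rng.normal(size=(30, 15))
    dend = agglomerate(build_cf_tree(X), X)
    oracle_merges, oracle_parts = naive_centroid_agglomeration(X)
    assert len(dend.merges) == len(oracle_merges) == 29
    for (i, j, d), (oi, oj, od) in zip(dend.merges, oracle_merges):
        assert {i, j} == {oi, oj}
        assert d == pytest.approx(od, abs=1e-9)


@pytest.mark.parametrize("k", [2, 3, 5])
def test_partitions_equal_naive_oracle_at_fixed_k(k):
    rng = np.random.default_rng(23)
    X = rng.normal(size=(30, 15))
    pcs = build_cf_tree(X)
    dend = agglomerate(pcs, X)
    _, oracle_parts = naive_centroid_agglomeration(X)
    sol = assign_clusters(X, pcs, dend, k)
    oracle = frozenset(frozenset(m) for m in oracle_parts[k].values())
    assert partition_sets(sol.assignments) == oracle


# ----------------------------------------------------------------------- BIC

def test_bic_closed_form_single_cluster():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(5, 15))
    var = X.var(axis=0)
    expected = -2 * (-5 * 0.5 * np.log(2 * var).sum()) + 2 * 15 * 1 * np.log(5)
    assert bic([list(range(5))], X) == pytest.approx(expected, rel=1e-10)


def test_bic_prefers_two_clusters_for_two_blobs():
    X, truth = _two_blobs(n_per=25, shift=3.0, seed=2)
    one = bic([list(range(50))], X)
    two = bic([list(np.where(truth == 0)[0]), list(np.where(truth == 1)[0])], X)
    assert two < one


def test_bic_guards():
    X = np.random.default_rng(0).normal(size=(6, 2))
    with pytest.raises(ClusteringError):
        bic([[0, 1, 2]], X)          # does not cover all points
    with pytest.raises(ClusteringError):
        bic([list(range(6)), []], X)  # empty cluster


def test_bic_degenerate_constant_clusters_guarded_by_floor():
    X = np.zeros((6, 3))
    X[3:, :] = 10.0  # constant within clusters, nonzero cohort variance
    value = bic([[0, 1, 2], [3, 4, 5]], X)
    assert np.isfinite(value)


# ------------------------------------------------------------------- auto-k

def test_two_well_separated_blobs_select_k2():
    X, _ = _two_blobs(n_per=20, shift=3.0, seed=4)
    sol = cluster_scores(X)
    assert sol.k_selected == 2


def test_three_equidistant_blobs_select_k3():
    selected = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        # centers on orthogonal 5-dimensional blocks: mutually equidistant
        centers = np.zeros((3, 15))
        for c in range(3):
            centers[c, 5 * c:5 * (c + 1)] = 5.0
        X = np.vstack([rng.normal(c, 1.0, (15, 15)) for c in centers])
        selected.append(cluster_scores(X).k_selected)
    values, counts = np.unique(selected, return_counts=True)
    assert values[np.argmax(counts)] == 3


def test_select_requires_kmax_at_least_two():
    X, _ = _two_blobs(n_per=5, seed=0)
    dend = agglomerate(build_cf_tree(X), X)
    with pytest.raises(ClusteringError):
        select_cluster_count(dend, k_max=1)


# -------------------------------------------------------------- assignment

def test_assignments_are_permutation_equivariant():
    X, _ = _two_blobs(n_per=15, shift=4.0, seed=6)
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(X))
    sol = cluster_scores(X)
    sol_p = cluster_scores(X[perm])
    assert sol.k_selected == sol_p.k_selected
    # partition identical up to relabelling of subjects
    back = np.empty(len(X), dtype=int)
    back[perm] = np.arange(len(X))
    assert partition_sets(sol.assignments) == partition_sets(sol_p.assignments[back])


def test_smaller_cluster_is_labelled_one():
    rng = np.random.default_rng(9)
    a = rng.normal(0, 1, (10, 15))
    b = rng.normal(8, 1, (30, 15))
    sol = cluster_scores(np.vstack([a, b]))
    assert sol.k_selected == 2
    assert sol.cluster_sizes[0] <= sol.cluster_sizes[1]
    assert set(np.unique(sol.assignments)) == {1, 2}
    assert sol.cluster_sizes.sum() == 40


def test_refinement_pass_reassigns_to_nearest_centroid():
    X, _ = _two_blobs(n_per=15, shift=4.0, seed=8)
    sol = cluster_scores(X, refine=True, k_fixed=2)
    cents = sol.centroids
    d = ((X[:, None, :] - cents[None, :, :]) ** 2).sum(-1)
    np.testing.assert_array_equal(np.argmin(d, axis=1) + 1, sol.assignments)


def test_planted_two_subtypes_recovered():
    X, truth = _two_blobs(n_per=40, shift=2.0, seed=10)
    sol = cluster_scores(X, k_fixed=2)
    from sklearn.metrics import adjusted_rand_score
    assert adjusted_rand_score(truth, sol.assignments) > 0.8


# --------------------------------------------------------------- silhouette

def test_silhouette_two_tight_blobs_near_one():
    X, truth = _two_blobs(n_per=10, shift=30.0, seed=12)
    assert mean_silhouette(X, truth) > 0.9


def test_silhouette_matches_bruteforce_and_sklearn():
    rng = np.random.default_rng(13)
    X = rng.normal(size=(6, 15))
    labels = np.array([0, 0, 1, 1, 2, 2])
    ours = mean_silhouette(X, labels)
    assert ours == pytest.approx(naive_mean_silhouette(X, labels), abs=1e-12)
    from sklearn.metrics import silhouette_score
    assert ours == pytest.approx(silhouette_score(X, labels), abs=1e-9)


def test_silhouette_singleton_cluster_contributes_zero():
    X = _embed([0.0, 0.1, 5.0])
    labels = np.array([0, 0, 1])
    ours = mean_silhouette(X, labels)
    assert ours == pytest.approx(naive_mean_silhouette(X, labels), abs=1e-12)


def test_silhouette_requires_two_clusters():
    X = np.random.default_rng(0).normal(size=(5, 3))
    with pytest.raises(ClusteringError):
        mean_silhouette(X, np.zeros(5, dtype=int))


def test_silhouette_bounded():
    rng = np.random.default_rng(14)
    X = rng.normal(size=(25, 4))
    labels = rng.integers(0, 3, 25)
    assert -1.0 <= mean_silhouette(X, labels) <= 1.0
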