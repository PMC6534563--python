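import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from battery_ontology.clustering import (
    ClusteringError,
    DistanceMatrix,
    adjusted_mutual_information,
    build_tree,
    consensus_cluster,
    dynamic_tree_cut,
    embed_2d,
    fixed_height_cut,
    loading_distance,
    silhouette,
    silhouette_sweep,
)


def _dist(d, names=None):
    d = np.asarray(d, dtype=float)
    if names is None:
        names = [f"v{i}" for i in range(d.shape[0])]
    return DistanceMatrix(d, names)


def _planted_blocks(rng, sizes, within=(0.02, 0.1), between=(0.8, 0.95)):
    labels = np.repeat(np.arange(len(sizes)), sizes)
    m = len(labels)
    d = np.where(
        labels[:, None] == labels[None, :],
        rng.uniform(*within, (m, m)),
        rng.uniform(*between, (m, m)),
    )
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    return _dist(d), labels


def _planted_loadings(rng, n_per=5, k=3, noise=0.05):
    L = np.zeros((n_per * k, k))
    for j in range(k):
        L[j * n_per:(j + 1) * n_per, j] = rng.uniform(0.5, 0.8, n_per)
    return L + rng.normal(0, noise, L.shape), np.repeat(np.arange(k), n_per)


class TestLoadingDistance:
    def test_identical_and_negated_rows_distance_zero(self):
        L = np.array([[0.7, 0.1, -0.2], [0.7, 0.1, -0.2], [-0.7, -0.1, 0.2]])
        d = loading_distance(L).d
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert d[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_three_entry_rows(self):
        # corr((1,0,0), (0,1,0)) = -1/2, so distance 1 - |r| = 1/2
        d = loading_distance(np.array([[1.0, 0, 0], [0, 1.0, 0]])).d
        assert d[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_constant_row_rejected_by_name(self):
        with pytest.raises(ClusteringError, match="flatdv"):
            loading_distance(np.array([[0.3, 0.3, 0.3], [0.1, 0.5, 0.2]]),
                             ["flatdv", "ok"])

    def test_invariant_to_row_scaling_and_sign(self):
        rng = np.random.default_rng(0)
        L = rng.normal(size=(6, 4))
        scale = np.array([2.0, -3.0, 0.5, 1.0, -1.0, 10.0])
        d1 = loading_distance(L).d
        d2 = loading_distance(L * scale[:, None]).d
        assert np.allclose(d1, d2, atol=1e-12)


class TestTree:
    def test_first_merge_is_closest_pair(self):
        d = _dist([[0, 0.1, 0.9], [0.1, 0, 0.9], [0.9, 0.9, 0]])
        Z = build_tree(d).tree
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_ultrametric_cophenetic_exact(self):
        # an ultrametric: pairs at 0.2, all cross distances at 0.8
        d = np.array([
            [0, 0.2, 0.8, 0.8],
            [0.2, 0, 0.8, 0.8],
            [0.8, 0.8, 0, 0.2],
            [0.8, 0.8, 0.2, 0],
        ])
        Z = build_tree(_dist(d)).tree
        coph = squareform(hierarchy.cophenet(Z))
        assert np.allclose(coph, d, atol=1e-12)

    def test_permutation_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(1)
        dist, labels = _planted_blocks(rng, [4, 4, 4])
        perm = rng.permutation(12)
        dist_p = _dist(dist.d[np.ix_(perm, perm)])
        cut = dynamic_tree_cut(build_tree(dist), dist)
        cut_p = dynamic_tree_cut(build_tree(dist_p), dist_p)
        ami = adjusted_mutual_information(
            cut.labels.to_numpy()[perm], cut_p.labels.to_numpy()
        )
        assert ami == pytest.approx(1.0)

    def test_single_point_rejected(self):
        with pytest.raises(ClusteringError):
            build_tree(_dist([[0.0]]))


class TestDynamicCut:
    def test_planted_blocks_recovered_exactly(self):
        rng = np.random.default_rng(2)
        dist, labels = _planted_blocks(rng, [6, 6, 6])
        cut = dynamic_tree_cut(build_tree(dist), dist)
        assert cut.n_clusters() == 3
        assert adjusted_mutual_information(cut.labels, labels) == pytest.approx(1.0)

    def test_single_tight_block_is_one_cluster(self):
        rng = np.random.default_rng(3)
        d = rng.uniform(0.02, 0.08, (9, 9))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        dist = _dist(d)
        cut = dynamic_tree_cut(build_tree(dist), dist)
        assert cut.n_clusters() == 1

    def test_min_cluster_size_too_large_errors(self):
        rng = np.random.default_rng(4)
        dist, _ = _planted_blocks(rng, [3, 3])
        with pytest.raises(ClusteringError):
            dynamic_tree_cut(build_tree(dist), dist, min_cluster_size=10)

    def test_agrees_with_fixed_cut_on_clean_data(self):
        rng = np.random.default_rng(5)
        dist, labels = _planted_blocks(rng, [5, 6, 7])
        tree = build_tree(dist)
        dyn = dynamic_tree_cut(tree, dist)
        fixed = fixed_height_cut(tree, dist, n_clusters=dyn.n_clusters())
        assert adjusted_mutual_information(dyn.labels, fixed.labels) >= 0.95


class TestFixedCut:
    def test_cut_above_root_gives_one_cluster(self):
        rng = np.random.default_rng(6)
        dist, _ = _planted_blocks(rng, [4, 4])
        tree = build_tree(dist)
        cut = fixed_height_cut(tree, dist, height=tree.tree[:, 2].max() + 0.01)
        assert cut.n_clusters() == 1

    def test_cut_below_first_merge_gives_singletons(self):
        rng = np.random.default_rng(7)
        dist, _ = _planted_blocks(rng, [4, 4])
        tree = build_tree(dist)
        cut = fixed_height_cut(tree, dist, height=tree.tree[:, 2].min() / 2)
        assert cut.n_clusters() == 8

    def test_silhouette_sweep_finds_planted_count(self):
        rng = np.random.default_rng(8)
        dist, _ = _planted_blocks(rng, [6, 6, 6])
        res = silhouette_sweep(build_tree(dist), dist)
        assert res["best"].n_clusters() == 3


class TestSilhouette:
    def test_two_far_tight_pairs(self):
        d = np.full((4, 4), 0.99)
        d[0, 1] = d[1, 0] = 0.01
        d[2, 3] = d[3, 2] = 0.01
        np.fill_diagonal(d, 0)
        res = silhouette(_dist(d), np.array([1, 1, 2, 2]))
        assert res["mean"] > 0.97

    def test_hand_worked_four_points(self):
        d = np.array([
            [0.0, 0.1, 0.7, 0.8],
            [0.1, 0.0, 0.6, 0.9],
            [0.7, 0.6, 0.0, 0.2],
            [0.8, 0.9, 0.2, 0.0],
        ])
        res = silhouette(_dist(d), np.array([1, 1, 2, 2]))
        # s(0): a=0.1, b=(0.7+0.8)/2=0.75 -> 0.65/0.75
        assert res["per_dv"].iloc[0] == pytest.approx((0.75 - 0.1) / 0.75)
        assert res["per_dv"].iloc[3] == pytest.approx((0.85 - 0.2) / 0.85)

    def test_random_labels_on_uniform_distances_near_zero(self):
        rng = np.random.default_rng(9)
        d = rng.uniform(0.45, 0.55, (40, 40))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        res = silhouette(_dist(d), rng.integers(1, 4, 40))
        assert abs(res["mean"]) < 0.1

    def test_single_cluster_undefined(self):
        rng = np.random.default_rng(10)
        dist, _ = _planted_blocks(rng, [4])
        with pytest.raises(ClusteringError):
            silhouette(dist, np.ones(4, dtype=int))


def _brute_force_ami(a, b):
    """AMI from the exact hypergeometric expected mutual information."""
    a = np.asarray(a)
    b = np.asarray(b)
    N = len(a)
    cats_a, cats_b = np.unique(a), np.unique(b)
    na = np.array([(a == x).sum() for x in cats_a])
    nb = np.array([(b == x).sum() for x in cats_b])
    # observed MI
    mi = 0.0
    for i, x in enumerate(cats_a):
        for j, y in enumerate(cats_b):
            nij = np.sum((a == x) & (b == y))
            if nij > 0:
                mi += (nij / N) * math.log(N * nij / (na[i] * nb[j]))
    # exact E[MI] over the hypergeometric distribution of each cell
    emi = 0.0
    for ai in na:
        for bj in nb:
            lo = max(ai + bj - N, 1)
            hi = min(ai, bj)
            for nij in range(lo, hi + 1):
                p = (
                    math.comb(bj, nij) * math.comb(N - bj, ai - nij)
                    / math.comb(N, ai)
                )
                emi += p * (nij / N) * math.log(N * nij / (ai * bj))
    ha = -sum((x / N) * math.log(x / N) for x in na)
    hb = -sum((x / N) * math.log(x / N) for x in nb)
    denom = (ha + hb) / 2 - emi
    if denom == 0:
        return 1.0 if mi == emi else 0.0
    return (mi - emi) / denom


class TestAMI:
    def test_identical_partitions(self):
        lab = np.array([1, 1, 2, 2, 3, 3])
        assert adjusted_mutual_information(lab, lab) == pytest.approx(1.0)

    def test_one_cluster_vs_singletons_is_zero(self):
        a = np.zeros(6, dtype=int)
        b = np.arange(6)
        assert adjusted_mutual_information(a, b) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "a,b",
        [
            ([0, 0, 1, 1, 2, 2], [0, 0, 0, 1, 1, 2]),
            ([0, 0, 1, 1], [0, 1, 0, 1]),
            ([0, 1, 2, 0, 1, 2, 0, 1], [0, 0, 1, 1, 2, 2, 0, 1]),
            ([0, 0, 0, 1, 1, 1, 2], [0, 1, 0, 1, 0, 1, 0]),
        ],
    )
    def test_matches_brute_force_hypergeometric_oracle(self, a, b):
        ours = adjusted_mutual_information(a, b)
        assert ours == pytest.approx(_brute_force_ami(a, b), abs=1e-10)

    def test_length_mismatch_errors(self):
        with pytest.raises(ClusteringError):
            adjusted_mutual_information([1, 2], [1, 2, 3])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        labels=st.lists(st.integers(0, 3), min_size=4, max_size=12),
        seed=st.integers(0, 100),
    )
    def test_symmetric_and_permutation_invariant(self, labels, seed):
        rng = np.random.default_rng(seed)
        a = np.array(labels)
        b = rng.integers(0, 3, len(a))
        assert adjusted_mutual_information(a, b) == pytest.approx(
            adjusted_mutual_information(b, a), abs=1e-12
        )
        remap = {x: x + 17 for x in set(a)}
        a2 = np.array([remap[x] for x in a])
        assert adjusted_mutual_information(a, b) == pytest.approx(
            adjusted_mutual_information(a2, b), abs=1e-12
        )


class TestConsensus:
    def test_degenerate_simulation_reproduces_original(self):
        rng = np.random.default_rng(11)
        L, labels = _planted_loadings(rng)
        names = [f"v{i}" for i in range(len(labels))]
        dist = loading_distance(L, names)
        cut = dynamic_tree_cut(build_tree(dist), dist)
        res = consensus_cluster(
            pd.DataFrame(L, index=names),
            pd.DataFrame(np.zeros_like(L), index=names),
            cut.labels, n_sim=120, drop_frac=0.0, seed=0,
        )
        assert res.ami_vs_original == pytest.approx(1.0)
        assert np.allclose(np.unique(res.cooccurrence.to_numpy()), [0.0, 1.0])

    def test_within_exceeds_between_on_planted_blocks(self):
        rng = np.random.default_rng(12)
        L, labels = _planted_loadings(rng)
        names = [f"v{i}" for i in range(len(labels))]
        dist = loading_distance(L, names)
        cut = dynamic_tree_cut(build_tree(dist), dist)
        res = consensus_cluster(
            pd.DataFrame(L, index=names),
            pd.DataFrame(np.full_like(L, 0.05), index=names),
            cut.labels, n_sim=300, drop_frac=0.2, seed=0,
        )
        assert res.within_mean - res.between_mean > 0.5
        co = res.cooccurrence.to_numpy()
        assert co.min() >= 0 and co.max() <= 1

    def test_monte_carlo_convergence(self):
        rng = np.random.default_rng(13)
        L, labels = _planted_loadings(rng)
        names = [f"v{i}" for i in range(len(labels))]
        dist = loading_distance(L, names)
        cut = dynamic_tree_cut(build_tree(dist), dist)
        mean = pd.DataFrame(L, index=names)
        sd = pd.DataFrame(np.full_like(L, 0.05), index=names)
        co_small = consensus_cluster(mean, sd, cut.labels, n_sim=500,
                                     seed=1).cooccurrence.to_numpy()
        co_big = consensus_cluster(mean, sd, cut.labels, n_sim=2000,
                                   seed=2).cooccurrence.to_numpy()
        assert np.abs(co_small - co_big).max() < 0.05


class TestEmbed:
    def test_mds_equilateral_triangle(self):
        d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        res = embed_2d(_dist(d * 0.5), method="mds", seed=0)
        xy = res["coords"].to_numpy()
        dists = [np.linalg.norm(xy[i] - xy[j]) for i, j in [(0, 1), (0, 2), (1, 2)]]
        assert max(dists) / min(dists) == pytest.approx(1.0, abs=1e-3)

    def test_pca_rank2_explains_everything(self):
        rng = np.random.default_rng(14)
        basis = rng.normal(size=(2, 6))
        X = rng.normal(size=(30, 2)) @ basis
        res = embed_2d(X, method="pca")
        assert res["variance_explained"].sum() == pytest.approx(1.0, abs=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ClusteringError):
            embed_2d(_dist(np.zeros((2, 2)) + np.array([[0, .5], [.5, 0]])),
                     method="mds")
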