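import numpy as np
import pytest

from twinsem.clustering import (ClusterTree, cluster_correlations, eigen_scree,
                                select_k)
from twinsem.datasets import REGION_LABELS, genetic_correlation_matrix
from twinsem.errors import ValidityError


def block_correlation(sizes, r_within, r_between=0.0):
    n = sum(sizes)
    R = np.full((n, n), r_between)
    start = 0
    for m in sizes:
        R[start:start + m, start:start + m] = r_within
        start += m
    np.fill_diagonal(R, 1.0)
    return R


def test_scree_identity_matrix_suggests_no_factors():
    res = eigen_scree(np.eye(11))
    np.testing.assert_allclose(res.eigenvalues, np.ones(11))
    assert res.kaiser_count == 0
    assert res.suggested == 0


def test_scree_block_eigenvalues_match_closed_form():
    """3 blocks of size m with within-block r: top eigenvalues 1+(m-1)r."""
    R = block_correlation([4, 4, 4], 0.6)
    res = eigen_scree(R)
    np.testing.assert_allclose(res.eigenvalues[:3], 1 + 3 * 0.6, atol=1e-10)
    assert res.kaiser_count == 3
    assert res.elbow_count == 3
    assert res.suggested == 3


def test_scree_rank_one_perturbation_top_eigenvalue():
    rho = 0.3
    n = 8
    R = (1 - rho) * np.eye(n) + rho * np.ones((n, n))
    res = eigen_scree(R)
    assert res.eigenvalues[0] == pytest.approx(1 + (n - 1) * rho, abs=1e-10)


def test_scree_rejects_asymmetric_input():
    R = np.eye(3)
    R[0, 1] = 0.5
    with pytest.raises(ValidityError, match="symmetric"):
        eigen_scree(R)


def test_identity_correlation_merges_at_height_one():
    tree = cluster_correlations(np.eye(5), labels=list("abcde"))
    np.testing.assert_allclose(tree.merge_heights, 1.0)
    part = tree.cut(5)
    assert len(set(part.values())) == 5  # any cut below 1 gives singletons


def test_synthetic_blocks_recovered_exactly_at_k():
    R = block_correlation([3, 4, 2], 0.7, 0.05)
    labels = [f"roi{i:02d}" for i in range(9)]
    tree = cluster_correlations(R, labels=labels)
    parts = tree.cut_sets(3)
    expect = [frozenset(labels[:3]), frozenset(labels[3:7]), frozenset(labels[7:])]
    assert sorted(parts, key=min) == sorted(expect, key=min)
    assert select_k(tree) == 3


def test_partition_invariant_to_leaf_input_order():
    rng = np.random.default_rng(0)
    R = block_correlation([3, 3, 3], 0.6, 0.1)
    labels = [f"r{i}" for i in range(9)]
    perm = rng.permutation(9)
    t1 = cluster_correlations(R, labels=labels)
    t2 = cluster_correlations(R[np.ix_(perm, perm)],
                              labels=[labels[i] for i in perm])
    for k in (2, 3, 4):
        assert sorted(t1.cut_sets(k), key=min) == sorted(t2.cut_sets(k), key=min)


def test_cuts_refine_as_k_grows():
    """Each leaf pair together at k stays together at k-1 (hierarchical)."""
    R = genetic_correlation_matrix().to_numpy()
    tree = cluster_correlations(R, labels=REGION_LABELS)
    for k in range(3, 7):
        fine = tree.cut(k)
        coarse = tree.cut(k - 1)
        for a in REGION_LABELS:
            for b in REGION_LABELS:
                if fine[a] == fine[b]:
                    assert coarse[a] == coarse[b]


def test_nan_entries_are_rejected_with_pair_listing():
    R = np.eye(3)
    R[0, 1] = R[1, 0] = np.nan
    with pytest.raises(ValidityError, match="undefined"):
        cluster_correlations(R, labels=["a", "b", "c"])


def test_negative_correlations_map_beyond_unit_distance():
    R = np.array([[1.0, -0.5], [-0.5, 1.0]])
    tree = cluster_correlations(R, labels=["x", "y"])
    assert tree.merge_heights[0] == pytest.approx(1.5)


def test_two_leaf_tree_forces_k_two():
    tree = cluster_correlations(np.array([[1.0, 0.4], [0.4, 1.0]]),
                                labels=["x", "y"])
    assert select_k(tree) == 2


def test_newick_export_contains_all_leaves():
    R = block_correlation([2, 2], 0.6)
    tree = cluster_correlations(R, labels=["a", "b", "c", "d"])
    nwk = tree.to_newick()
    assert nwk.endswith(";")
    for lab in "abcd":
        assert lab in nwk


def test_published_genetic_matrix_clusters_into_three_groups():
    """The printed genetic correlation matrix separates cortical lobes,
    basal ganglia, and the limbic/diencephalic group at k = 3."""
    df = genetic_correlation_matrix()
    tree = cluster_correlations(df.to_numpy(), labels=list(df.index))
    parts = tree.cut_sets(3)
    expect = [frozenset({"TEMP", "PARI", "FRON", "OCCI"}),
              frozenset({"CAU", "PAL", "PUT"}),
              frozenset({"ACC", "AMY", "HIP", "THA"})]
    assert sorted(parts, key=min) == sorted(expect, key=min)
    assert select_k(tree) == 3
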