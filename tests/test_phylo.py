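"""Distances, neighbour joining, bootstrap, tree clusters and association."""

import numpy as np
import pytest

from heg_atlas import (
    DistanceMatrix,
    association_test,
    bootstrap_support,
    extract_tree_clusters,
    neighbor_joining,
    pairwise_distance_matrix,
)
from heg_atlas._align import global_align
from heg_atlas.phylo import cramers_v, leaf_path_lengths, to_newick_with_support

from conftest import mutated, random_protein
from _oracles import gotoh_global_score, random_additive_tree, tree_bipartitions


def test_identical_sequences_have_zero_distance():
    dm = pairwise_distance_matrix({"a": "MKTLV" * 20, "b": "MKTLV" * 20, "c": "MKTLV" * 20})
    assert np.allclose(dm.d, 0.0)


def test_p_distance_arithmetic():
    rng = np.random.default_rng(0)
    a = random_protein(rng, 100)
    b = list(a)
    for i in range(0, 100, 10):  # exactly 10 substitutions
        b[i] = next(x for x in "ACDEFGHIKLMNPQRSTVWY" if x != a[i])
    dm = pairwise_distance_matrix({"a": a, "b": "".join(b), "c": a})
    assert dm.d[dm.labels.index("a"), dm.labels.index("b")] == pytest.approx(0.10)


def test_distances_match_independent_recomputation():
    """Dual-route check on a mutated family: the global aligner reproduces
    the independent DP score, and the gap-excluded p-distance equals the
    positional mismatch fraction (substitution-only family, so the optimal
    global alignment is gapless)."""
    rng = np.random.default_rng(5)
    base = random_protein(rng, 150)
    prots = {f"s{i}": mutated(base, 0.1, rng) for i in range(8)}
    dm = pairwise_distance_matrix(prots)
    for i, a in enumerate(dm.labels):
        for j in range(i + 1, len(dm.labels)):
            b = dm.labels[j]
            assert global_align(prots[a], prots[b]).score == pytest.approx(
                gotoh_global_score(prots[a], prots[b]), abs=1e-9
            )
            hamming = sum(x != y for x, y in zip(prots[a], prots[b])) / 150
            assert abs(dm.d[i, j] - hamming) < 1e-12


def test_distance_matrix_requires_three_sequences():
    with pytest.raises(ValueError):
        pairwise_distance_matrix({"a": "MKT", "b": "MKT"})


def test_distance_matrix_validation():
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(labels=["a", "b"], d=np.array([[0.0, 1.0], [2.0, 0.0]]))


def test_nj_three_taxa_closed_form():
    d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
    tree = neighbor_joining(DistanceMatrix(labels=["a", "b", "c"], d=d))
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
    assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
    assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)


def test_nj_recovers_four_taxon_additive_tree():
    # tree: A and B join an inner node u (1 from root side); C, D on the other
    labels = ["A", "B", "C", "D"]
    d = np.array(
        [
            [0.0, 3.0, 5.0, 3.0],
            [3.0, 0.0, 6.0, 4.0],
            [5.0, 6.0, 0.0, 4.0],
            [3.0, 4.0, 4.0, 0.0],
        ]
    )
    tree = neighbor_joining(DistanceMatrix(labels=labels, d=d))
    assert frozenset({frozenset({"A", "B"}), frozenset({"C", "D"})}) in tree_bipartitions(
        tree, labels
    )
    dm = leaf_path_lengths(tree)
    idx = [dm.labels.index(l) for l in labels]
    assert np.allclose(dm.d[np.ix_(idx, idx)], d, atol=1e-9)


@pytest.mark.parametrize("seed", range(6))
def test_nj_exact_on_random_additive_metrics(seed):
    rng = np.random.default_rng(1000 + seed)
    labels, d, biparts = random_additive_tree(int(rng.integers(4, 9)), rng)
    tree = neighbor_joining(DistanceMatrix(labels=labels, d=d))
    assert tree_bipartitions(tree, labels) == biparts
    dm = leaf_path_lengths(tree)
    idx = [dm.labels.index(l) for l in labels]
    assert np.max(np.abs(dm.d[np.ix_(idx, idx)] - d)) < 1e-9


def test_nj_agrees_with_skbio_on_additive_matrix():
    """Independent-package cross-check of the topology."""
    import skbio

    rng = np.random.default_rng(77)
    labels, d, _ = random_additive_tree(7, rng)
    mine = neighbor_joining(DistanceMatrix(labels=labels, d=d))
    ref = skbio.tree.nj(skbio.DistanceMatrix((d + d.T) / 2, ids=labels))
    assert tree_bipartitions(mine, labels) == tree_bipartitions(ref, labels)


def test_asymmetric_matrix_is_rejected():
    bad = np.array([[0, 1, 1], [2, 0, 1], [1, 1, 0.0]])
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(labels=["a", "b", "c"], d=bad)


def _two_clade_alignment(rng, n_per_clade=4, length=120):
    a = random_protein(rng, length)
    b = random_protein(rng, length)
    aligned = {}
    for i in range(n_per_clade):
        aligned[f"a{i}"] = mutated(a, 0.03, rng)
        aligned[f"b{i}"] = mutated(b, 0.03, rng)
    return aligned


def test_bootstrap_saturates_on_well_separated_clades():
    rng = np.random.default_rng(11)
    aligned = _two_clade_alignment(rng)
    tree = bootstrap_support(aligned, n_replicates=100, seed=3)
    leafset = frozenset(aligned)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if frozenset({side, leafset - side}) == frozenset(
            {frozenset({"a0", "a1", "a2", "a3"}), frozenset({"b0", "b1", "b2", "b3"})}
        ):
            assert node.support == 100
            break
    else:
        pytest.fail("separating edge not found")


def test_bootstrap_is_reproducible_from_seed():
    rng = np.random.default_rng(12)
    aligned = _two_clade_alignment(rng)
    t1 = bootstrap_support(aligned, n_replicates=50, seed=9)
    t2 = bootstrap_support(aligned, n_replicates=50, seed=9)
    s1 = sorted(n.support for n in t1.non_tips(include_self=False))
    s2 = sorted(n.support for n in t2.non_tips(include_self=False))
    assert s1 == s2


def test_bootstrap_rejects_bad_inputs():
    with pytest.raises(ValueError):
        bootstrap_support({"a": "MK", "b": "MK", "c": "MK"}, n_replicates=0, seed=1)
    with pytest.raises(ValueError):
        bootstrap_support({"a": "MKT", "b": "MK", "c": "MKT"}, n_replicates=10, seed=1)


def test_bootstrap_supports_invariant_to_leaf_input_order():
    rng = np.random.default_rng(13)
    aligned = _two_clade_alignment(rng, n_per_clade=3)
    shuffled = dict(reversed(list(aligned.items())))
    s1 = bootstrap_support(aligned, n_replicates=30, seed=4)
    s2 = bootstrap_support(shuffled, n_replicates=30, seed=4)
    b1 = {
        frozenset(t.name for t in n.tips()): n.support
        for n in s1.non_tips(include_self=False)
    }
    b2 = {
        frozenset(t.name for t in n.tips()): n.support
        for n in s2.non_tips(include_self=False)
    }
    assert b1 == b2


def test_newick_serialization_round_trips():
    from io import StringIO

    import skbio

    d = np.array([[0.0, 0.2, 0.7], [0.2, 0.0, 0.8], [0.7, 0.8, 0.0]])
    tree = neighbor_joining(DistanceMatrix(labels=["x", "y", "z"], d=d))
    text = to_newick_with_support(tree)
    back = skbio.TreeNode.read(StringIO(text))
    assert {t.name for t in back.tips()} == {"x", "y", "z"}


def test_tree_cluster_cut_boundaries():
    rng = np.random.default_rng(21)
    labels, d, _ = random_additive_tree(6, rng)
    tree = neighbor_joining(DistanceMatrix(labels=labels, d=d))
    whole = extract_tree_clusters(tree, cut_distance=float(d.max()) + 1.0)
    assert set(whole.labels.values()) == {"I"}
    tiny = extract_tree_clusters(tree, cut_distance=1e-6)
    assert len(set(tiny.labels.values())) == len(labels)


def test_tree_clusters_recover_planted_lineages():
    rng = np.random.default_rng(22)
    clades = {}
    for c in range(3):
        anc = random_protein(rng, 150)
        for i in range(4):
            clades[f"c{c}_{i}"] = mutated(anc, 0.05, rng)
    dm = pairwise_distance_matrix(clades)
    tree = neighbor_joining(dm)
    labeling = extract_tree_clusters(tree, cut_distance=0.3)
    groups = {}
    for leaf, lab in labeling.labels.items():
        groups.setdefault(lab, set()).add(leaf.split("_")[0])
    assert len(groups) == 3
    assert all(len(v) == 1 for v in groups.values())


def test_cluster_labeling_is_a_partition_of_leaves():
    rng = np.random.default_rng(23)
    labels, d, _ = random_additive_tree(8, rng)
    tree = neighbor_joining(DistanceMatrix(labels=labels, d=d))
    labeling = extract_tree_clusters(tree, cut_distance=1.5)
    assert sorted(labeling.labels) == sorted(labels)


def test_association_perfect_and_closed_form():
    labels = {f"i{k}": ("X" if k < 10 else "Y") for k in range(20)}
    v, p = association_test(labels, dict(labels), n_perm=999, seed=1)
    assert v == pytest.approx(1.0)
    assert p == pytest.approx(1 / 1000)
    a = np.array(["u"] * 10 + ["v"] * 10)
    b = np.array(["x"] * 10 + ["y"] * 10)
    assert cramers_v(a, b) == pytest.approx(1.0)  # 2x2 table [[10,0],[0,10]]


def test_association_single_category_is_an_error():
    with pytest.raises(ValueError):
        association_test({"a": "X", "b": "X"}, {"a": "P", "b": "Q"}, n_perm=10, seed=0)
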