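"""Similarity gate, Markov clustering and gene-content phage clustering."""

import numpy as np
import pytest

from heg_atlas import (
    all_vs_all_similarity,
    build_gene_content_matrix,
    mcl,
    two_way_hcl,
)
from heg_atlas._align import InvalidSequenceError, local_align
from heg_atlas.orthologs import OrthologPartition

from conftest import build_genome, mutated, random_protein
from _oracles import similarity_edges_bruteforce


def test_identical_sequences_make_a_full_identity_edge():
    rng = np.random.default_rng(0)
    seq = random_protein(rng, 100)
    edges = all_vs_all_similarity({"a": seq, "b": seq})
    assert len(edges) == 1
    e = edges[0]
    assert e.pct_identity == 100.0 and e.cov_a == 1.0 and e.cov_b == 1.0


def test_coverage_gate_is_bidirectional():
    """A 60-aa sequence fully contained in a 200-aa one covers only 30% of
    the long sequence, so the edge is rejected."""
    rng = np.random.default_rng(1)
    short = random_protein(rng, 60)
    long = random_protein(rng, 70) + short + random_protein(rng, 70)
    res = local_align(long, short)
    assert res.cov_b == 1.0 and res.cov_a <= 0.5
    assert all_vs_all_similarity({"long": long, "short": short}) == []


def test_similarity_is_symmetric():
    rng = np.random.default_rng(2)
    a = random_protein(rng, 120)
    b = mutated(a, 0.3, rng)
    r1, r2 = local_align(a, b), local_align(b, a)
    assert r1.score == r2.score
    assert r1.pct_identity == pytest.approx(r2.pct_identity)
    assert (r1.cov_a, r1.cov_b) == (r2.cov_b, r2.cov_a)


@pytest.mark.parametrize("seed", [10, 11, 12])
def test_kept_edges_match_bruteforce_aligner(seed):
    """Divergences straddling the 50% identity gate: the kept-edge set must
    equal an independent quadratic-DP recomputation."""
    rng = np.random.default_rng(seed)
    base = random_protein(rng, 120)
    proteins = {
        f"s{i}": mutated(base, div, rng)
        for i, div in enumerate([0.0, 0.2, 0.35, 0.65, 0.8])
    }
    proteins["unrelated"] = random_protein(rng, 130)
    mine = {(e.a, e.b) for e in all_vs_all_similarity(proteins)}
    assert mine == similarity_edges_bruteforce(proteins)


def test_prescreen_keeps_all_related_pairs():
    """The word-seed prescreen is lossless well above the identity gate
    (the regime the cohort pipeline runs it in)."""
    rng = np.random.default_rng(13)
    base = random_protein(rng, 150)
    proteins = {f"s{i}": mutated(base, 0.15, rng) for i in range(6)}
    exact = {(e.a, e.b) for e in all_vs_all_similarity(proteins)}
    seeded = {(e.a, e.b) for e in all_vs_all_similarity(proteins, prescreen=True)}
    assert exact == seeded and len(exact) == 15


def test_invalid_residue_names_the_gene():
    with pytest.raises(InvalidSequenceError, match="geneX"):
        all_vs_all_similarity({"geneX": "MKTX*", "geneY": "MKTA"})


# ---------------------------------------------------------------------------
# MCL
# ---------------------------------------------------------------------------

def _clique_edges(names):
    return [(a, b, 1.0) for i, a in enumerate(names) for b in names[i + 1 :]]


def test_mcl_separates_disjoint_cliques():
    edges = _clique_edges(["a1", "a2", "a3"]) + _clique_edges(["b1", "b2", "b3"])
    part = mcl(edges)
    assert {frozenset(c) for c in part.clusters} == {
        frozenset({"a1", "a2", "a3"}),
        frozenset({"b1", "b2", "b3"}),
    }


def test_mcl_empty_graph_gives_singletons():
    part = mcl([], nodes=["w", "x", "y", "z"])
    assert sorted(len(c) for c in part.clusters) == [1, 1, 1, 1]


@pytest.mark.parametrize("inflation", [1.5, 2.0, 3.0, 4.0])
def test_mcl_clique_components_for_any_inflation(inflation):
    edges = (
        _clique_edges(["a1", "a2", "a3", "a4"])
        + _clique_edges(["b1", "b2"])
        + _clique_edges(["c1", "c2", "c3"])
    )
    part = mcl(edges, inflation=inflation)
    assert {frozenset(c) for c in part.clusters} == {
        frozenset({"a1", "a2", "a3", "a4"}),
        frozenset({"b1", "b2"}),
        frozenset({"c1", "c2", "c3"}),
    }


def test_mcl_output_is_a_partition_of_the_nodes():
    rng = np.random.default_rng(5)
    nodes = [f"n{i}" for i in range(40)]
    edges = [
        (nodes[i], nodes[j], float(rng.uniform(0.5, 3)))
        for i in range(40)
        for j in range(i + 1, 40)
        if rng.random() < 0.1
    ]
    part = mcl(edges, nodes=nodes)
    seen = [g for c in part.clusters for g in c]
    assert sorted(seen) == sorted(nodes)


def test_partition_rejects_overlapping_clusters():
    with pytest.raises(ValueError):
        OrthologPartition([frozenset({"a", "b"}), frozenset({"b", "c"})])


def test_mcl_deterministic_cluster_numbering():
    edges = _clique_edges(["z1", "z2", "z3"]) + _clique_edges(["a1", "a2", "a3"])
    part = mcl(edges)
    # equal sizes: numbering falls back to smallest member
    assert part.members("OC0001") == frozenset({"a1", "a2", "a3"})


# ---------------------------------------------------------------------------
# Gene-content matrix and two-way HCL
# ---------------------------------------------------------------------------

def test_gene_content_matrix_hand_example():
    gA = build_genome("A", ["g1", "g2"])
    gB = build_genome("B", ["g1", "g2"])
    part = OrthologPartition(
        [frozenset({"A|g1", "B|g1"}), frozenset({"A|g2"}), frozenset({"B|g2"})]
    )
    m = build_gene_content_matrix(part, [gA, gB])
    assert m.loc["A"].tolist() == [1, 1, 0]
    assert m.loc["B"].tolist() == [1, 0, 1]


def test_gene_content_matrix_counting_invariants(small_cohort, small_partition):
    genomes, truth = small_cohort
    part = small_partition
    m = build_gene_content_matrix(part, genomes)
    for genome in genomes:
        assert m.loc[genome.genome_id].sum() == len(genome.genes)
    # a core family's column sums to the number of genomes
    core_gene = truth.genes[(truth.genes.is_core) & (truth.genes.core_rank == 0)].gene_id.iloc[0]
    cid = part.cluster_of(core_gene)
    assert m[cid].sum() == len(genomes)


def test_gene_content_matrix_orphan_gene_is_an_error():
    gA = build_genome("A", ["g1"])
    part = OrthologPartition([frozenset({"A|g1", "GHOST|g9"})])
    with pytest.raises(ValueError, match="GHOST"):
        build_gene_content_matrix(part, [gA])


def test_hcl_zero_distance_pair_merges_first():
    import pandas as pd

    m = pd.DataFrame(
        [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]],
        index=["a", "b", "c"],
        columns=["c1", "c2", "c3", "c4"],
    )
    clustering = two_way_hcl(m, k=2)
    assert clustering.labels["a"] == clustering.labels["b"] != clustering.labels["c"]
    assert clustering.linkage_record[0, 2] == 0.0  # first merge at height 0


def test_hcl_recovers_planted_lineages(small_cohort, small_partition):
    genomes, truth = small_cohort
    m = build_gene_content_matrix(small_partition, genomes)
    labels = two_way_hcl(m, k=3).labels
    lineage = dict(zip(truth.genomes.genome_id, truth.genomes.lineage))
    # same-lineage genomes share a label; different lineages never do
    for ga in genomes:
        for gb in genomes:
            same = lineage[ga.genome_id] == lineage[gb.genome_id]
            assert (labels[ga.genome_id] == labels[gb.genome_id]) == same


def test_hcl_boundaries_and_row_permutation_invariance():
    import pandas as pd

    rng = np.random.default_rng(8)
    m = pd.DataFrame(
        (rng.random((6, 12)) < 0.5).astype(int),
        index=[f"G{i}" for i in range(6)],
        columns=[f"c{i}" for i in range(12)],
    )
    assert len(set(two_way_hcl(m, k=6).labels.values())) == 6
    with pytest.raises(ValueError):
        two_way_hcl(m, k=0)
    shuffled = m.sample(frac=1.0, random_state=3)
    assert two_way_hcl(m, k=3).labels == two_way_hcl(shuffled, k=3).labels
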