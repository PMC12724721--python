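"""HNHE anchoring, locus consolidation and flank-to-reference comparison."""

import numpy as np
import pytest

from heg_atlas.classify import HnheAssignment
from heg_atlas.loci import (
    TERMINUS,
    anchor_heg,
    compare_flank_to_reference,
    consolidate_loci,
)
from heg_atlas.orthologs import OrthologPartition
from heg_atlas.scaffold import CoreScaffold

from conftest import build_genome
from _oracles import gotoh_local, _nt_sub, NT_OPEN, NT_EXT


def _setup(tags):
    genome = build_genome("G", tags)
    clusters = [frozenset({f"G|{t}"}) for t in tags]
    partition = OrthologPartition(clusters)
    cid = {t: partition.cluster_of(f"G|{t}") for t in tags}
    core = {cid[t] for t in tags if t.startswith("c")}
    return genome, partition, cid, core


def _assignment(gene_id, family="IHMU"):
    return HnheAssignment(gene_id, family, family if family != "TRUNCATED" else "IHMU",
                          0.9, 80.0, None, 300.0)


def test_anchor_with_adjacent_core_genes():
    genome, partition, cid, core = _setup(["c5", "heg", "c6"])
    a = anchor_heg(genome, "G|heg", core, partition)
    assert (a.upstream_core, a.downstream_core) == (cid["c5"], cid["c6"])
    assert (a.intervening_upstream, a.intervening_downstream) == (0, 0)


def test_anchor_counts_intervening_accessory_genes():
    genome, partition, cid, core = _setup(["c5", "x1", "x2", "heg", "c6"])
    a = anchor_heg(genome, "G|heg", core, partition)
    assert a.upstream_core == cid["c5"] and a.downstream_core == cid["c6"]
    assert (a.intervening_upstream, a.intervening_downstream) == (2, 0)


def test_anchor_at_genome_end_is_terminus():
    genome, partition, cid, core = _setup(["heg", "c1", "c2"])
    a = anchor_heg(genome, "G|heg", core, partition)
    assert a.upstream_core == TERMINUS and a.downstream_core == cid["c1"]


def test_core_gene_cannot_be_anchored():
    genome, partition, cid, core = _setup(["c1", "c2", "c3"])
    with pytest.raises(ValueError, match="core"):
        anchor_heg(genome, "G|c2", core, partition)


def test_gve2_heg_is_anchored_between_terl_and_portal_clusters(flagship_analysis, flagship_cohort):
    """Every DNA-packaging (GVE2-like) HNHE sits between the terminase large
    subunit and portal protein clusters, as in real cohorts."""
    res = flagship_analysis
    reps = res.representative_products
    terl = next(c for c in res.core_set if reps[c] == "terminase large subunit")
    portal = next(c for c in res.core_set if reps[c] == "portal protein")
    gve2_locus = [l for l in res.loci if l.family_counts.get("GVE2", 0) > 0]
    assert len(gve2_locus) == 1
    assert gve2_locus[0].flank_pair == (terl, portal)


def _scaffold(n):
    core = [f"OC{i:04d}" for i in range(1, n + 1)]
    return CoreScaffold(ordered_core=core, anchor=core[0]), core


def test_consolidate_groups_and_orders_by_scaffold_position():
    scaffold, core = _scaffold(12)
    from heg_atlas.loci import FlankingAnchor

    anchors = [
        FlankingAnchor("g1", core[8], core[9], 0, 0),
        FlankingAnchor("g2", core[8], core[9], 0, 0),
        FlankingAnchor("g3", core[4], core[5], 0, 0),
        FlankingAnchor("g4", core[4], core[5], 0, 0),
        FlankingAnchor("g5", core[4], core[5], 0, 0),
    ]
    assignments = [_assignment(f"g{i}") for i in range(1, 6)]
    loci = consolidate_loci(anchors, scaffold, assignments)
    assert [l.locus_id for l in loci] == ["H1", "H2"]
    assert loci[0].flank_pair == (core[4], core[5])
    assert loci[0].members == {"g3", "g4", "g5"}
    assert loci[1].members == {"g1", "g2"}


def test_consolidate_merges_nested_anchor_from_core_deletion():
    """(c5,c7) from a genome missing c6 merges with (c5,c6) by containment."""
    scaffold, core = _scaffold(10)
    from heg_atlas.loci import FlankingAnchor

    anchors = [
        FlankingAnchor("g1", core[4], core[5], 0, 0),
        FlankingAnchor("g2", core[4], core[6], 0, 1),
    ]
    loci = consolidate_loci(anchors, scaffold, [_assignment("g1"), _assignment("g2")])
    assert len(loci) == 1
    assert loci[0].members == {"g1", "g2"}
    assert loci[0].flank_pair == (core[4], core[5])  # tightest observed pair


def test_truncated_only_group_does_not_create_a_locus():
    scaffold, core = _scaffold(10)
    from heg_atlas.loci import FlankingAnchor

    anchors = [
        FlankingAnchor("g1", core[2], core[3], 0, 0),
        FlankingAnchor("t1", core[7], core[8], 0, 0),
    ]
    assignments = [_assignment("g1"), _assignment("t1", "TRUNCATED")]
    loci = consolidate_loci(anchors, scaffold, assignments)
    assert [l.members for l in loci] == [{"g1"}]
    loci_all = consolidate_loci(anchors, scaffold, assignments, truncated_only_loci=True)
    assert len(loci_all) == 2


def test_unknown_cluster_in_anchor_is_an_error():
    scaffold, core = _scaffold(5)
    from heg_atlas.loci import FlankingAnchor

    with pytest.raises(ValueError, match="unknown"):
        consolidate_loci(
            [FlankingAnchor("g", "OC9999", core[1], 0, 0)], scaffold, [_assignment("g")]
        )


def test_every_intact_hnhe_in_exactly_one_locus(flagship_analysis):
    res = flagship_analysis
    intact = {a.gene_id for a in res.assignments if a.family in ("IHMU", "PACI", "GVE2")}
    covered = [l.members & intact for l in res.loci]
    union = set().union(*covered) if covered else set()
    assert union == intact
    assert sum(len(c) for c in covered) == len(intact)


def test_locus_ids_stable_under_genome_input_order(small_cohort, small_partition):
    from heg_atlas import classify_cohort
    from heg_atlas.loci import anchor_heg as anchor_fn
    from heg_atlas.pipeline import representative_products
    from heg_atlas.scaffold import consensus_core_order, identify_core_clusters

    genomes, _ = small_cohort
    partition = small_partition
    assignments = classify_cohort(genomes)
    hnhe = {a.gene_id for a in assignments}
    core = {
        c for c in identify_core_clusters(partition, genomes)
        if not (partition.members(c) & hnhe)
    }
    reps = representative_products(partition, genomes)
    anchor_cl = next(c for c in core if reps[c] == "terminase large subunit")

    def run(order):
        scaffold = consensus_core_order(order, partition, core, anchor_cl)
        genome_of = {g.gene_id: gm for gm in order for g in gm.genes}
        anchors = [anchor_fn(genome_of[a.gene_id], a.gene_id, core, partition) for a in assignments]
        return consolidate_loci(anchors, scaffold, assignments)

    fwd = run(genomes)
    rev = run(list(reversed(genomes)))
    assert [(l.locus_id, l.members) for l in fwd] == [(l.locus_id, l.members) for l in rev]


# ---------------------------------------------------------------------------
# Flank-to-reference DNA comparison
# ---------------------------------------------------------------------------

def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def test_identical_gene_scores_full_identity():
    rng = np.random.default_rng(0)
    gene = _random_dna(rng, 300)
    cmp = compare_flank_to_reference(gene, gene)
    assert cmp.pct_identity == 100.0 and cmp.coverage == 1.0


def test_partially_randomized_gene_matches_independent_dp():
    """20% of codons randomized: identity within 2 points of the
    independent DP aligner's value."""
    rng = np.random.default_rng(1)
    gene = _random_dna(rng, 300)
    mutant = list(gene)
    for codon in range(100):
        if rng.random() < 0.2:
            mutant[3 * codon : 3 * codon + 3] = list(_random_dna(rng, 3))
    mutant = "".join(mutant)
    cmp = compare_flank_to_reference(mutant, gene)
    score, matches, columns, qa, qb = gotoh_local(
        mutant, gene, sub=_nt_sub, open_=NT_OPEN, ext=NT_EXT
    )
    oracle_identity = 100.0 * matches / columns
    assert cmp.pct_identity == pytest.approx(oracle_identity, abs=2.0)


def test_prefix_match_reports_low_coverage_without_filtering():
    rng = np.random.default_rng(2)
    ref = _random_dna(rng, 300)
    query = ref[:90] + _random_dna(rng, 210)
    cmp = compare_flank_to_reference(query, ref)
    assert cmp.coverage == pytest.approx(0.3, abs=0.1)


def test_empty_sequence_is_an_error():
    with pytest.raises(ValueError):
        compare_flank_to_reference("", "ACGT")
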