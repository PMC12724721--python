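"""End-to-end cohort analysis: orthologs -> scaffold -> HNHEs -> loci -> tree.

`run_cohort_analysis` chains every stage on an annotated cohort and returns
all intermediate artifacts, so the same entry point drives the examples, the
recovery tests and the acceptance script.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .classify import TRUNCATED, HnheAssignment, ReferenceHnhe, classify_cohort, load_references
from .io import PhageGenome
from .loci import InsertionLocus, anchor_heg, consolidate_loci
from .orthologs import (
    OrthologPartition,
    PhageClustering,
    all_vs_all_similarity,
    build_gene_content_matrix,
    mcl,
    two_way_hcl,
)
from .phylo import (
    ClusterLabeling,
    association_test,
    extract_tree_clusters,
    neighbor_joining,
    pairwise_distance_matrix,
)
from .scaffold import (
    CoreScaffold,
    assign_functional_modules,
    consensus_core_order,
    identify_core_clusters,
)

MARKER_PRODUCTS = {
    "terminase large subunit": "morphogenesis",
    "portal protein": "morphogenesis",
    "DNA polymerase": "replication",
    "transcriptional regulator": "regulation",
}
ANCHOR_PRODUCT = "terminase large subunit"


@dataclass
class CohortAnalysis:
    partition: OrthologPartition
    gene_content: pd.DataFrame
    phage_clusters: PhageClustering
    core_set: set[str]
    scaffold: CoreScaffold
    assignments: list[HnheAssignment]
    loci: list[InsertionLocus]
    tree: object | None = None                  # skbio TreeNode for tree_family
    tree_clusters: ClusterLabeling | None = None
    association: tuple[float, float] | None = None   # (Cramer's V, p)
    representative_products: dict = field(default_factory=dict)


def representative_products(
    partition: OrthologPartition, genomes: list[PhageGenome]
) -> dict[str, str]:
    """Most common product annotation per ortholog cluster."""
    product_of = {g.gene_id: g.product for gm in genomes for g in gm.genes}
    out = {}
    for cid, members in zip(partition.cluster_ids, partition.clusters):
        counts = Counter(product_of.get(m, "") for m in members)
        out[cid] = counts.most_common(1)[0][0]
    return out


def run_cohort_analysis(
    genomes: list[PhageGenome],
    k_phage_clusters: int,
    references: dict[str, ReferenceHnhe] | None = None,
    min_identity: float = 50.0,
    min_coverage: float = 0.5,
    inflation: float = 2.0,
    prescreen: bool = True,
    presence_fraction: float = 1.0,
    tree_family: str = "IHMU",
    cut_distance: float = 0.21,
    n_perm: int = 1000,
    seed: int = 0,
) -> CohortAnalysis:
    """Run the full comparative analysis on an annotated cohort.

    The core set excludes any ortholog cluster containing a classified HNHE
    gene (a universally present HEG — the DNA-packaging one — would
    otherwise satisfy the single-copy full-presence core rule and could not
    be anchored).  The per-family tree is built for ``tree_family`` when at
    least three intact members exist, cut into clusters at ``cut_distance``
    (a leaf-to-leaf path-length bound), and tested for association with the
    starter culture of each gene's genome.
    """
    refs = references or load_references()
    proteins = {g.gene_id: g.protein_seq for gm in genomes for g in gm.genes}
    edges = all_vs_all_similarity(proteins, min_identity, min_coverage, prescreen=prescreen)
    partition = mcl(edges, nodes=proteins.keys(), inflation=inflation)
    matrix = build_gene_content_matrix(partition, genomes)
    phage_clusters = two_way_hcl(matrix, k=k_phage_clusters)

    assignments = classify_cohort(genomes, refs)
    hnhe_genes = {a.gene_id for a in assignments}
    core = identify_core_clusters(partition, genomes, presence_fraction)
    core = {
        cid for cid in core if not (partition.members(cid) & hnhe_genes)
    }

    reps = representative_products(partition, genomes)
    anchor = _cluster_by_product(reps, core, ANCHOR_PRODUCT)
    scaffold = consensus_core_order(genomes, partition, core, anchor)
    marker_map = {}
    for product, module in MARKER_PRODUCTS.items():
        cid = _cluster_by_product(reps, core, product, required=False)
        if cid is not None:
            marker_map[cid] = module
    scaffold = assign_functional_modules(scaffold, marker_map)

    genome_of = {g.gene_id: gm for gm in genomes for g in gm.genes}
    anchors = [
        anchor_heg(genome_of[a.gene_id], a.gene_id, core, partition) for a in assignments
    ]
    loci = consolidate_loci(anchors, scaffold, assignments)

    result = CohortAnalysis(
        partition=partition,
        gene_content=matrix,
        phage_clusters=phage_clusters,
        core_set=core,
        scaffold=scaffold,
        assignments=assignments,
        loci=loci,
        representative_products=reps,
    )

    family_members = {
        a.gene_id: proteins[a.gene_id] for a in assignments if a.family == tree_family
    }
    if len(family_members) >= 3:
        dm = pairwise_distance_matrix(family_members)
        tree = neighbor_joining(dm)
        labeling = extract_tree_clusters(tree, cut_distance)
        starters = {
            gid: genome_of[gid].metadata.get("starter", "unknown")
            for gid in family_members
        }
        result.tree = tree
        result.tree_clusters = labeling
        if len(set(labeling.labels.values())) > 1 and len(set(starters.values())) > 1:
            result.association = association_test(
                labeling.labels, starters, n_perm=n_perm, seed=seed
            )
    return result


def _cluster_by_product(
    reps: dict[str, str], core: set[str], product: str, required: bool = True
) -> str | None:
    hits = sorted(cid for cid in core if reps.get(cid, "") == product)
    if not hits:
        if required:
            raise ValueError(f"no core cluster annotated as {product!r}")
        return None
    return hits[0]
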