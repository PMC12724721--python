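"""Core-genome scaffold: the coordinate frame for insertion loci.

Core ortholog clusters are the families present single-copy in (by default)
every genome.  Their consensus order, oriented on an anchor cluster — the
terminase large subunit by default, a guaranteed landmark next to the
DNA-packaging HNHE — gives each core family a rank along the genome, and
functional modules (morphogenesis / replication / regulation) are painted
onto that order from a small set of marker genes.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .io import PhageGenome
from .orthologs import OrthologPartition

MODULES = ("morphogenesis", "replication", "regulation")
UNASSIGNED = "unassigned"


@dataclass
class CoreScaffold:
    """Consensus-ordered single-copy core clusters with module labels."""

    ordered_core: list[str]
    anchor: str
    module_of: dict[str, str] = field(default_factory=dict)
    conflicts: dict[str, int] = field(default_factory=dict)  # genome_id -> breakpoints

    def __post_init__(self) -> None:
        for cid in self.ordered_core:
            self.module_of.setdefault(cid, UNASSIGNED)

    def rank(self, cluster_id: str) -> int:
        return self.ordered_core.index(cluster_id)

    def to_frame(self, representative_products: Mapping[str, str] | None = None) -> pd.DataFrame:
        rows = []
        for rank, cid in enumerate(self.ordered_core):
            rows.append(
                {
                    "rank": rank,
                    "cluster_id": cid,
                    "representative_product": (representative_products or {}).get(cid, ""),
                    "module": self.module_of[cid],
                }
            )
        return pd.DataFrame(rows)


def identify_core_clusters(
    partition: OrthologPartition,
    genomes: Sequence[PhageGenome],
    presence_fraction: float = 1.0,
    single_copy: bool = True,
) -> set[str]:
    """Ortholog clusters with exactly one member in >= presence_fraction of genomes.

    With ``single_copy`` (default) any cluster duplicated in even one genome
    is excluded — core families are required to be strictly single-copy.
    """
    gene_to_genome = {g.gene_id: gm.genome_id for gm in genomes for g in gm.genes}
    n = len(genomes)
    core: set[str] = set()
    for cid, members in zip(partition.cluster_ids, partition.clusters):
        per_genome = Counter(gene_to_genome[g] for g in members)
        if single_copy and any(c > 1 for c in per_genome.values()):
            continue
        n_single = sum(1 for c in per_genome.values() if c == 1)
        if n_single >= presence_fraction * n:
            core.add(cid)
    if not core:
        raise ValueError(
            "no core clusters at presence_fraction="
            f"{presence_fraction}; relax the threshold (e.g. 0.9) for degraded cohorts"
        )
    return core


def _oriented_core_order(
    genome: PhageGenome, partition: OrthologPartition, core_set: set[str], anchor: str
) -> tuple[str, ...] | None:
    """Genome's core clusters, rotated so the anchor comes first and its strand
    reads forward.  None when the anchor is missing from this genome."""
    order: list[str] = []
    anchor_strand = None
    for gene in genome.genes:  # genes already sorted by start
        cid = partition.cluster_of(gene.gene_id) if gene.gene_id in partition.gene_ids else None
        if cid in core_set:
            order.append(cid)
            if cid == anchor:
                anchor_strand = gene.strand
    if anchor not in order:
        return None
    if anchor_strand == "-":
        order = order[::-1]
    i = order.index(anchor)
    return tuple(order[i:] + order[:i])


def consensus_core_order(
    genomes: Sequence[PhageGenome],
    partition: OrthologPartition,
    core_set: set[str],
    anchor: str,
) -> CoreScaffold:
    """Consensus order of the core clusters across the cohort.

    Each genome's core genes are projected to a cluster sequence, rotated so
    the anchor leads and reads forward; the consensus is the order seen in a
    plurality of genomes.  Genomes disagreeing with the consensus are
    recorded with their breakpoint count (adjacencies absent from the
    consensus).
    """
    if anchor not in core_set:
        raise ValueError(f"anchor cluster {anchor} is not in the core set")
    orders: dict[str, tuple[str, ...]] = {}
    for genome in sorted(genomes, key=lambda g: g.genome_id):
        o = _oriented_core_order(genome, partition, core_set, anchor)
        if o is not None:
            orders[genome.genome_id] = o
    if not orders:
        raise ValueError("anchor cluster found in no genome")
    tally = Counter(orders.values())
    top = tally.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        conflict_set = [list(o) for o, c in top if c == top[0][1]]
        raise ValueError(f"no plurality core order; tied orders: {conflict_set}")
    consensus = list(top[0][0])
    adjacencies = {(consensus[i], consensus[i + 1]) for i in range(len(consensus) - 1)}
    conflicts: dict[str, int] = {}
    for gid, order in orders.items():
        if list(order) != consensus:
            bp = sum(
                1
                for i in range(len(order) - 1)
                if (order[i], order[i + 1]) not in adjacencies
            )
            conflicts[gid] = bp
    return CoreScaffold(ordered_core=consensus, anchor=anchor, conflicts=conflicts)


def assign_functional_modules(
    scaffold: CoreScaffold, marker_map: Mapping[str, str]
) -> CoreScaffold:
    """Label core clusters with functional modules from marker genes.

    Markers pin their own module; between two markers of different modules
    the boundary sits at the midpoint of their ranks (the downstream module
    starting at ``ceil((p1+p2)/2)``); spans flanked by same-module markers
    inherit that module, and the first/last modules extend to the scaffold
    ends.  Modules named by no marker are never assigned.
    """
    if not marker_map:
        raise ValueError("marker_map must name at least one core cluster")
    for cid, module in marker_map.items():
        if cid not in scaffold.ordered_core:
            raise ValueError(f"marker {cid} ({module}) is not a core cluster")
        if module not in MODULES:
            raise ValueError(f"unknown module {module!r}; expected one of {MODULES}")
    positions = sorted((scaffold.rank(cid), marker_map[cid]) for cid in marker_map)
    n = len(scaffold.ordered_core)
    labels = [UNASSIGNED] * n
    # paint from each marker outward; boundaries at rank midpoints
    for idx, (pos, module) in enumerate(positions):
        lo = 0 if idx == 0 else (
            positions[idx - 1][0] + 1
            if positions[idx - 1][1] == module
            else math.ceil((positions[idx - 1][0] + pos) / 2)
        )
        hi = n if idx == len(positions) - 1 else (
            positions[idx + 1][0]
            if positions[idx + 1][1] == module
            else math.ceil((pos + positions[idx + 1][0]) / 2)
        )
        for p in range(lo, hi):
            labels[p] = module
    module_of = {cid: labels[i] for i, cid in enumerate(scaffold.ordered_core)}
    return CoreScaffold(
        ordered_core=list(scaffold.ordered_core),
        anchor=scaffold.anchor,
        module_of=module_of,
        conflicts=dict(scaffold.conflicts),
    )
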