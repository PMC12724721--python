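"""Anchoring HNHE genes to core flanks and consolidating insertion loci.

Every HNHE gene is walked left and right along its genome's gene order until
a core-cluster gene is met on each side (or a genome end); cohort-wide, the
resulting flank pairs are grouped into named insertion loci H1, H2, ...
ordered along the consensus core scaffold.  Two flank pairs merge when one's
interval on the consensus order contains the other's — the nested-anchor
case produced by a sporadic core-gene loss in a single genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align

from .classify import TRUNCATED, HnheAssignment
from .io import PhageGenome
from .orthologs import OrthologPartition
from .scaffold import CoreScaffold

TERMINUS = "terminus"


@dataclass(frozen=True)
class FlankingAnchor:
    """Nearest core genes on both sides of one HNHE gene."""

    gene_id: str
    upstream_core: str      # cluster_id or "terminus"
    downstream_core: str
    intervening_upstream: int
    intervening_downstream: int


@dataclass
class InsertionLocus:
    """One consolidated insertion position between two core clusters."""

    locus_id: str           # "H1", "H2", ...
    flank_pair: tuple[str, str]
    members: frozenset[str]
    module: str
    family_counts: dict


def anchor_heg(
    genome: PhageGenome,
    hnhe_gene_id: str,
    core_set: set[str],
    partition: OrthologPartition,
) -> FlankingAnchor:
    """Anchor one HNHE gene to its nearest core genes.

    Walks the genome's start-sorted gene order outward from the HNHE gene,
    counting intervening non-core genes; a genome end yields the anchor
    ``"terminus"``.
    """
    ids = [g.gene_id for g in genome.genes]
    try:
        idx = ids.index(hnhe_gene_id)
    except ValueError:
        raise ValueError(f"{hnhe_gene_id} is not a gene of {genome.genome_id}") from None

    def cluster_of(gene_id: str) -> str | None:
        try:
            return partition.cluster_of(gene_id)
        except KeyError:
            return None

    own = cluster_of(hnhe_gene_id)
    if own in core_set:
        raise ValueError(
            f"{hnhe_gene_id} belongs to core cluster {own}; core and mobile genes are exclusive"
        )
    up, n_up = TERMINUS, 0
    for i in range(idx - 1, -1, -1):
        cid = cluster_of(ids[i])
        if cid in core_set:
            up = cid
            break
        n_up += 1
    down, n_down = TERMINUS, 0
    for i in range(idx + 1, len(ids)):
        cid = cluster_of(ids[i])
        if cid in core_set:
            down = cid
            break
        n_down += 1
    if up == TERMINUS and down == TERMINUS:
        raise ValueError(f"{hnhe_gene_id}: no core anchor on either side")
    return FlankingAnchor(hnhe_gene_id, up, down, n_up, n_down)


def consolidate_loci(
    anchors: Sequence[FlankingAnchor],
    scaffold: CoreScaffold,
    assignments: Sequence[HnheAssignment],
    truncated_only_loci: bool = False,
) -> list[InsertionLocus]:
    """Group flank anchors into insertion loci H1..Hn along the consensus order.

    Anchors sharing a flank pair form a locus; a pair whose consensus-order
    interval contains another's merges with it (containment tolerates local
    core-gene loss).  Loci are numbered by the consensus position of their
    upstream flank.  Truncated HNHEs are anchored and tallied but, unless
    ``truncated_only_loci`` is set, a group containing only truncated genes
    does not become a locus of its own.
    """
    n = len(scaffold.ordered_core)
    pos = {cid: i for i, cid in enumerate(scaffold.ordered_core)}
    family_of = {a.gene_id: a.family for a in assignments}

    def interval(anchor: FlankingAnchor) -> tuple[int, int]:
        if anchor.upstream_core == TERMINUS:
            lo, hi = -1, pos[anchor.downstream_core]
        elif anchor.downstream_core == TERMINUS:
            lo, hi = pos[anchor.upstream_core], n
        else:
            for side in (anchor.upstream_core, anchor.downstream_core):
                if side not in pos:
                    raise ValueError(f"anchor references unknown cluster {side}")
            a, b = pos[anchor.upstream_core], pos[anchor.downstream_core]
            lo, hi = min(a, b), max(a, b)
        return lo, hi

    groups: dict[tuple[int, int], list[FlankingAnchor]] = {}
    for anchor in anchors:
        for side in (anchor.upstream_core, anchor.downstream_core):
            if side != TERMINUS and side not in pos:
                raise ValueError(f"anchor references unknown cluster {side}")
        groups.setdefault(interval(anchor), []).append(anchor)

    # merge by containment (union-find over distinct intervals)
    keys = sorted(groups)
    parent = {k: k for k in keys}

    def find(k):
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    for a in keys:
        for b in keys:
            if a != b and a[0] <= b[0] and b[1] <= a[1]:  # a contains b
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
    merged: dict[tuple[int, int], list[FlankingAnchor]] = {}
    for k in keys:
        merged.setdefault(find(k), []).extend(groups[k])

    loci: list[tuple[tuple[int, int], list[FlankingAnchor]]] = []
    for root, members in merged.items():
        # canonical flank pair: the tightest interval observed in the group
        tight = max(
            (interval(a) for a in members), key=lambda iv: (iv[0], -iv[1])
        )
        fams = {family_of.get(a.gene_id, TRUNCATED) for a in members}
        if not truncated_only_loci and fams == {TRUNCATED}:
            continue
        loci.append((tight, members))
    loci.sort(key=lambda x: (x[0][0], x[0][1], min(a.gene_id for a in x[1])))

    out: list[InsertionLocus] = []
    for i, (tight, members) in enumerate(loci):
        lo, hi = tight
        up = TERMINUS if lo < 0 else scaffold.ordered_core[lo]
        down = TERMINUS if hi >= n else scaffold.ordered_core[hi]
        module_src = up if up != TERMINUS else down
        counts: dict[str, int] = {}
        for a in members:
            fam = family_of.get(a.gene_id, TRUNCATED)
            counts[fam] = counts.get(fam, 0) + 1
        out.append(
            InsertionLocus(
                locus_id=f"H{i + 1}",
                flank_pair=(up, down),
                members=frozenset(a.gene_id for a in members),
                module=scaffold.module_of.get(module_src, "unassigned"),
                family_counts=counts,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Nucleotide comparison of flanking core genes to a reference genome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceComparison:
    cluster_id: str
    reference_gene: str
    pct_identity: float
    coverage: float


@lru_cache(maxsize=1)
def _nt_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -7.0
    aligner.extend_gap_score = -2.0
    return aligner


def compare_flank_to_reference(
    core_gene_dna: str,
    reference_dna: str,
    cluster_id: str = "",
    reference_gene: str = "",
) -> ReferenceComparison:
    """Best local DNA alignment of a core gene against a reference gene/genome.

    Identity is computed over aligned columns (gaps in the denominator);
    coverage is the aligned fraction of the query.  Values are reported, not
    filtered.
    """
    if not core_gene_dna or not reference_dna:
        raise ValueError("empty sequence")
    best = _nt_aligner().align(core_gene_dna.upper(), reference_dna.upper())[0]
    seg_q, seg_r = best.aligned
    if len(seg_q) == 0:
        return ReferenceComparison(cluster_id, reference_gene, 0.0, 0.0)
    matches = columns = 0
    q, r = core_gene_dna.upper(), reference_dna.upper()
    for (sq, eq), (sr, er) in zip(seg_q, seg_r):
        columns += eq - sq
        matches += sum(1 for x, y in zip(q[sq:eq], r[sr:er]) if x == y)
    for i in range(1, len(seg_q)):
        columns += int(seg_q[i][0] - seg_q[i - 1][1]) + int(seg_r[i][0] - seg_r[i - 1][1])
    span = int(seg_q[-1][1] - seg_q[0][0])
    return ReferenceComparison(
        cluster_id=cluster_id,
        reference_gene=reference_gene,
        pct_identity=100.0 * matches / columns,
        coverage=span / len(q),
    )


def loci_frame(loci: Iterable[InsertionLocus]) -> pd.DataFrame:
    rows = []
    for locus in loci:
        rows.append(
            {
                "locus_id": locus.locus_id,
                "upstream": locus.flank_pair[0],
                "downstream": locus.flank_pair[1],
                "module": locus.module,
                "n_IHMU": locus.family_counts.get("IHMU", 0),
                "n_PACI": locus.family_counts.get("PACI", 0),
                "n_GVE2": locus.family_counts.get("GVE2", 0),
                "n_truncated": locus.family_counts.get(TRUNCATED, 0),
                "members": ",".join(sorted(locus.members)),
            }
        )
    return pd.DataFrame(rows)
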